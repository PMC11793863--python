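# Packaged fNIRS montage: 3x11 optode grid (ETG-4000 style), 52 channels,
# 32 in-use channels over the prefrontal cortex. Source-detector separation 3 cm.
# Users may supply their own montage file with the same schema.
source_detector_distance_cm: 3.0
channels:
  C1: {source: S1, detector: D6}
  C2: {source: S1, detector: D1}
  C3: {source: S2, detector: D1}
  C4: {source: S2, detector: D2}
  C5: {source: S3, detector: D2}
  C6: {source: S3, detector: D3}
  C7: {source: S4, detector: D3}
  C8: {source: S4, detector: D4}
  C9: {source: S5, detector: D4}
  C10: {source: S5, detector: D5}
  C11: {source: S6, detector: D5}
  C12: {source: S7, detector: D1}
  C13: {source: S2, detector: D7}
  C14: {source: S4, detector: D9}
  C15: {source: S7, detector: D6}
  C16: {source: S7, detector: D7}
  C17: {source: S8, detector: D7}
  C18: {source: S8, detector: D8}
  C19: {source: S9, detector: D8}
  C20: {source: S9, detector: D9}
  C21: {source: S10, detector: D9}
  C22: {source: S10, detector: D10}
  C23: {source: S11, detector: D10}
  C24: {source: S11, detector: D11}
  C25: {source: S8, detector: D2}
  C26: {source: S3, detector: D8}
  C27: {source: S9, detector: D3}
  C28: {source: S10, detector: D4}
  C29: {source: S5, detector: D10}
  C30: {source: S11, detector: D5}
  C31: {source: S6, detector: D11}
  C32: {source: S12, detector: D6}
  C33: {source: S7, detector: D12}
  C34: {source: S13, detector: D7}
  C35: {source: S8, detector: D13}
  C36: {source: S14, detector: D8}
  C37: {source: S9, detector: D14}
  C38: {source: S15, detector: D9}
  C39: {source: S10, detector: D15}
  C40: {source: S16, detector: D10}
  C41: {source: S11, detector: D16}
  C42: {source: S17, detector: D11}
  C43: {source: S12, detector: D12}
  C44: {source: S13, detector: D12}
  C45: {source: S13, detector: D13}
  C46: {source: S14, detector: D13}
  C47: {source: S14, detector: D14}
  C48: {source: S15, detector: D14}
  C49: {source: S15, detector: D15}
  C50: {source: S16, detector: D15}
  C51: {source: S16, detector: D16}
  C52: {source: S17, detector: D16}
in_use: [C1, C2, C3, C4, C5, C6, C7, C8, C9, C10, C11, C12, C13, C14, C15, C16, C17, C18, C19, C20, C21, C22, C23, C24, C25, C26, C27, C28, C29, C30, C31, C37]
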