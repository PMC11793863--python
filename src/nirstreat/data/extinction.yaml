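# Molar extinction coefficients for oxy-/deoxy-hemoglobin (cm^-1 / M),
# standard compiled in-vitro values at the two measurement wavelengths.
# The absolute molar scale of recovered ΔHbO/ΔHbR depends on these values;
# they are shipped as editable configuration.
extinction:
  695:
    HbO: 319.6
    HbR: 1897.8
  830:
    HbO: 974.0
    HbR: 693.04
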