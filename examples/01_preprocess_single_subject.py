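"""Preprocess one synthetic subject: raw intensity to baseline-corrected ΔHbO.

Simulates a single responder under the verbal-fluency paradigm, runs the
full preprocessing chain (optical density, motion correction, detrend,
0.01-0.1 Hz band-pass, Beer-Lambert conversion, two-point baseline
correction, channel QC) and prints what came out.
"""

import numpy as np

from nirstreat import load_montage, preprocess_recording
from nirstreat.simulate import SimulationConfig, simulate_subject

montage = load_montage()
subject = simulate_subject(SimulationConfig(), "R", np.random.default_rng(0),
                           subject_id="demo", montage=montage)
rec = subject.recording
print(f"subject age {rec.age:.1f} y, {rec.intensity.shape[0]} channels, "
      f"{rec.intensity.shape[2]} samples at {rec.sampling_rate:g} Hz")

hb, qc = preprocess_recording(rec, montage)
task = rec.paradigm.task_slice
in_use = [i for i, c in enumerate(montage.channel_ids) if c in set(montage.in_use_mask)]
trace = hb.hbo[in_use][:, task].mean(axis=0)

print(f"channels kept by QC: {len(qc.kept_channels)} / {len(qc.channel_ids)}")
print(f"discard reasons: { {r for r in qc.reasons if r != 'ok'} or 'none' }")
print(f"task-period ΔHbO peak (PFC average): {trace.max() * 1e6:.3f} µM")
print(f"planted response amplitude:          {subject.truth['amplitude'] * 1e6:.3f} µM")
print("The recovered peak sits below the planted amplitude because the "
      "0.01-0.1 Hz band-pass attenuates the slow 60 s task response.")
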