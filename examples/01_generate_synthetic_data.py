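"""Generate a small synthetic HD-sEMG dataset and inspect its structure.

Builds the compact 16-channel profile (8 subjects x 8 gestures x 10
repetitions, 4x4 electrode grid, 1 s at 1 kHz) and prints per-channel RMS
for two gestures of one subject: the gesture-specific spatial activation
pattern is directly visible as which electrodes carry energy.
"""

import numpy as np

from emgmeta import SynthConfig, generate_dataset

config = SynthConfig.small(seed=0)
recordings = generate_dataset(config)
print(f"{len(recordings)} recordings, {config.n_channels} channels, "
      f"{config.n_samples} samples each")

for gesture in (0, 1):
    rec = next(r for r in recordings if r.subject == 0 and r.gesture == gesture
               and r.repetition == 0)
    rms = np.sqrt(np.mean(rec.signal ** 2, axis=1)).reshape(config.grid_rows,
                                                            config.grid_cols)
    print(f"\ngesture {gesture}: per-electrode RMS over the 4x4 grid")
    print(np.round(rms, 2))

print("\nHigh-RMS electrodes mark the gesture's activation centre; the "
      "pattern shifts and rescales between subjects.")
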