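"""Show that the ratio features ignore the subject-to-camera distance.

Renders the same walker close up (2x scale) and far away (1x), measures
both, and prints the per-feature worst relative disagreement: raw pixel
measurements double, the ratios do not move.
"""

from dataclasses import replace

import numpy as np

import gaitspeed as gs

walker = gs.WalkerParams(gait_frequency=5 / 240, leg_swing_amplitude=0.28,
                         arm_swing_amplitude=0.64, seed=8)
near = gs.measure_sequence(gs.generate_sequence(replace(walker, scale=2.0), 60))
far = gs.measure_sequence(gs.generate_sequence(walker, 60))

print("raw measurements (frame 10):")
print("  far :", far.iloc[10][["full_body_height", "full_body_width", "apparent_body_area"]].to_dict())
print("  near:", near.iloc[10][["full_body_height", "full_body_width", "apparent_body_area"]].to_dict())
print()
print("ratio features, worst per-frame relative deviation between the scales:")
for name in ("HW1", "HW2", "HW3", "A1", "A2"):
    a, b = far[name].to_numpy(), near[name].to_numpy()
    big = np.maximum(np.abs(a), np.abs(b))
    rel = np.abs(a - b) / np.where(big > 0, big, 1.0)
    if name in ("A1", "A2"):
        rel[big < 0.01] = 0.0  # below the pixel-quantization floor
    print(f"  {name}: {100 * rel.max():.2f} %")
print()
print("Heights and areas scale with the camera distance; every ratio stays")
print("within a few percent — the property that makes the features usable")
print("across recording setups.")
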