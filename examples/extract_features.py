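"""Measure one synthetic walker frame by frame and inspect the ratios.

Renders a normal-speed walker, extracts the seven raw body measurements
and the five camera-distance-invariant ratios per frame, and prints the
first few rows plus per-signal statistics.
"""

import gaitspeed as gs

walker = gs.WalkerParams(gait_frequency=6 / 240, leg_swing_amplitude=0.30,
                         arm_swing_amplitude=0.69, seed=1)
frames = gs.generate_sequence(walker, 120)
features = gs.measure_sequence(frames)

print(features.head(8).to_string(index=False))
print()
for name in ("HW1", "HW2", "HW3", "A1", "A2"):
    sig = features[name].to_numpy()
    if (sig > 0).all():
        amp = f"{gs.amplitude_percent(sig):5.1f} %"
    else:
        amp = "undefined (touches 0)"
    print(f"{name}: amplitude {amp:<22} peaks {gs.count_peaks(sig):2d} per {len(sig)} frames")
print()
print("The walker completes 3 gait cycles in these 120 frames, so the")
print("width/area-driven signals peak about 6 times (twice per cycle);")
print("A2 is exactly 0 whenever the legs cross.")
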