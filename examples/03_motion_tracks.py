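"""Construct per-readout motion tracks for the three experiment conditions.

Instantaneous motion flips between two poses, drift ramps linearly, and the
synthetic realistic pattern emulates unsedated pediatric patients: long still
periods, a handful of fast jumps, slow drift episodes, pitch dominant.
Tracks import/export as TSV (readout, rx, ry, rz, tx, ty, tz).
"""

from motionsampling import (
    fraction_in_motion,
    make_drift,
    make_instantaneous,
    make_realistic,
    peak_to_peak,
    resample_track,
    save_track_tsv,
)

n_readouts = 25600  # one pose per TR, Cartesian scan at n=160

inst = make_instantaneous(n_readouts, 10.0, axis="x", switch_fractions=(0.5,))
print(f"instantaneous +/-10 deg, 50/50 split: states "
      f"{sorted(set(float(v) for v in inst.rotations[:, 0]))} deg")

drift = make_drift(n_readouts, 5.0, axis="x")
print(f"drift: pitch runs {drift.rotations[0, 0]:+.1f} -> {drift.rotations[-1, 0]:+.1f} deg")

real = make_realistic(n_readouts, seed=0)
print(f"realistic (seed 0): peak-to-peak pitch {peak_to_peak(real, 'pitch'):.1f} deg, "
      f"{100 * fraction_in_motion(real):.1f}% of readouts in motion")

stretched = resample_track(real, 40320)  # stack-of-stars readout count
print(f"nearest-neighbor stretch to 40320 readouts keeps the pose range: "
      f"{peak_to_peak(stretched, 'pitch'):.1f} deg")

save_track_tsv(real, "realistic_track.tsv")
print("wrote realistic_track.tsv (reusable via --track-file / load_track_tsv)")
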