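"""Generate the six sampling patterns and check the Nyquist spoke counts.

Each trajectory is a time-ordered list of readouts (one per TR) with exact
k-space coordinates.  Radial spoke counts follow the theoretical Nyquist
limit: ceil(n*pi/2) in-plane spokes for stack-of-stars and ceil(n^2*pi/2)
half-sphere spokes for kooshball; full spokes are extended by sqrt(2) or
sqrt(3) to reach the Cartesian grid corners.
"""

import numpy as np

from motionsampling import make_trajectory, nyquist_spokes, tiny_golden_angle

print(f"stack-of-stars spokes at n=130: {nyquist_spokes(130, 'stack_of_stars')}")
print(f"kooshball spokes at n=130:      {nyquist_spokes(130, 'kooshball')}")
print(f"readouts per scan at n=160: cartesian {nyquist_spokes(160, 'cartesian')}, "
      f"stack-of-stars {nyquist_spokes(160, 'stack_of_stars') * 160}, "
      f"kooshball {nyquist_spokes(160, 'kooshball')}")
print(f"tiny golden angle, level 3: {tiny_golden_angle(3):.4f} deg "
      "(the non-smooth angle increment)")

for kind in ("cartesian", "stack_of_stars", "kooshball"):
    for ordering in ("smooth", "non_smooth"):
        traj = make_trajectory(kind, 32, ordering)
        r = np.linalg.norm(traj.flat_coords(), axis=1).max()
        print(f"{kind:15s} {ordering:10s}: {traj.n_readouts:5d} readouts x "
              f"{traj.samples_per_readout:3d} samples, kmax={r:.1f} cycles/FOV")
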