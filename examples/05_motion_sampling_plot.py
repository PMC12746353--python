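"""Build and render a motion-sampling plot.

Instead of plotting pose against time, every k-space sample is colored by the
pose it was acquired in -- the distribution of motion states across k-space
is what determines the artifact.  The discontinuity report locates the
largest pose jumps between spatially adjacent samples; jumps near the k-space
center are the worst case.
"""

from motionsampling import (
    build_msplot,
    cartesian_trajectory,
    discontinuity_report,
    make_instantaneous,
    render_msplot,
)

n = 64
traj = cartesian_trajectory(n, "smooth")

for split, label in [((0.5,), "50/50"), ((0.1,), "10/90")]:
    track = make_instantaneous(traj.n_readouts, 10.0, axis="x", switch_fractions=split)
    plot = build_msplot(traj, track, parameter="pitch", reference="absolute")
    for entry in discontinuity_report(plot):
        flag = "CENTER-CRITICAL" if entry["center_critical"] else "peripheral"
        print(f"{label} split: {entry['jump']:.0f} deg jump across {entry['axis']} = "
              f"{entry['location']:+.1f} ({flag})")

track = make_instantaneous(traj.n_readouts, 10.0, axis="x", switch_fractions=(0.5,))
plot = build_msplot(traj, track, parameter="pitch", reference="mean_pose")
render_msplot(plot, "msplot_cartesian_5050.png")
print("wrote msplot_cartesian_5050.png (3D scatter + kx-ky / kx-kz / ky-kz projections)")
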