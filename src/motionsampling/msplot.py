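"""Motion-sampling plots: mapping per-readout pose onto k-space.

A motion-sampling plot attaches to every k-space sample the pose parameter
(pitch, roll or yaw in degrees, or the RMS-displacement-over-a-sphere summary
in mm) of the readout during which it was acquired.  It replaces the
motion-time plot: instead of showing *when* the subject moved it shows *which
part of k-space* was acquired in each pose, which is what determines the
artifact.  By convention values are referenced to the mean pose over the scan
(zero mean across readouts); absolute values are available for clarity when
comparing temporal shifts.

The discontinuity report scans the plot for large pose jumps between
spatially adjacent samples -- the primary artifact predictor -- and flags
jumps close to the k-space center, where an inconsistency is worst-case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion import MotionTrack
from .trajectory import Trajectory

PARAMETERS = ("pitch", "roll", "yaw", "rms_displacement")


@dataclass
class MotionSamplingPlot:
    """Pose value attached to every k-space sample of a trajectory.

    ``values`` is per-readout (one pose per TR); per-sample values are the
    readout value repeated over its samples.  The trajectory reference is kept
    so projections and the discontinuity report know the sampling geometry.
    """

    trajectory: Trajectory
    values: np.ndarray  # (n_readouts,)
    parameter: str
    reference: str

    @property
    def coords(self) -> np.ndarray:
        return self.trajectory.flat_coords()

    def sample_values(self) -> np.ndarray:
        return np.repeat(self.values, self.trajectory.samples_per_readout)


def build_msplot(
    trajectory: Trajectory,
    track: MotionTrack,
    parameter: str = "pitch",
    reference: str = "mean_pose",
    sphere_radius_mm: float = 64.0,
) -> MotionSamplingPlot:
    """Attach the chosen pose parameter of each readout to its k-space samples.

    ``reference="mean_pose"`` re-references the track to its mean pose first
    (for the angle parameters this zeroes the readout-weighted mean of the
    plotted values); ``"absolute"`` keeps raw values.
    """
    if track.n_readouts != trajectory.n_readouts:
        raise ValueError(
            f"track length {track.n_readouts} does not match "
            f"trajectory readout count {trajectory.n_readouts}"
        )
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}, got {parameter!r}")
    if reference not in ("mean_pose", "absolute"):
        raise ValueError(f"unknown reference {reference!r}")
    t = track.to_mean_reference() if reference == "mean_pose" else track
    values = t.parameter(parameter, sphere_radius=sphere_radius_mm)
    return MotionSamplingPlot(trajectory, values, parameter, reference)


_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def render_msplot(
    plot: MotionSamplingPlot,
    path,
    planes: tuple[str, ...] = ("xy", "xz", "yz"),
    max_points: int = 200_000,
    seed: int = 0,
    dpi: int = 110,
):
    """Render the plot: a 3D scatter plus orthogonal-plane projections.

    Colors use a symmetric diverging scale about the reference pose
    (limits +/- max |value|).  Large clouds are subsampled for display only
    (uniform random, fixed seed); the plot data are never subsampled.
    Returns the matplotlib figure after saving it to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    coords = plot.coords
    vals = plot.sample_values()
    if coords.shape[0] == 0:
        raise ValueError("cannot render an empty motion-sampling plot")
    if coords.shape[0] > max_points:
        idx = np.random.default_rng(seed).choice(coords.shape[0], max_points, replace=False)
        idx.sort()
        coords, vals = coords[idx], vals[idx]
    vmax = float(np.max(np.abs(vals)))
    if vmax == 0.0:
        vmax = 1.0
    unit = "mm" if plot.parameter == "rms_displacement" else "deg"

    fig = plt.figure(figsize=(4 * (len(planes) + 1), 4.2))
    ax3 = fig.add_subplot(1, len(planes) + 1, 1, projection="3d")
    sc = ax3.scatter(
        coords[:, 0], coords[:, 1], coords[:, 2], c=vals, s=1,
        cmap="RdBu_r", vmin=-vmax, vmax=vmax, rasterized=True,
    )
    ax3.set_title(f"{plot.parameter} ({plot.reference})")
    ax3.set_xlabel("kx")
    ax3.set_ylabel("ky")
    ax3.set_zlabel("kz")
    for i, plane in enumerate(planes, start=2):
        a, b = _PLANES[plane]
        ax = fig.add_subplot(1, len(planes) + 1, i)
        ax.scatter(coords[:, a], coords[:, b], c=vals, s=1,
                   cmap="RdBu_r", vmin=-vmax, vmax=vmax, rasterized=True)
        ax.set_xlabel(f"k{plane[0]}")
        ax.set_ylabel(f"k{plane[1]}")
        ax.set_aspect("equal")
    fig.colorbar(sc, ax=fig.axes, shrink=0.7, label=f"{plot.parameter} [{unit}]")
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path


def _cartesian_report(plot: MotionSamplingPlot, tol: float) -> list[dict]:
    traj = plot.trajectory
    n, c = traj.n, traj.n // 2
    ky = np.round(traj.coords[:, 0, 1]).astype(int) + c
    kz = np.round(traj.coords[:, 0, 2]).astype(int) + c
    grid = np.full((n, n), np.nan)
    grid[ky, kz] = plot.values
    entries = []
    for axis, g in (("ky", grid), ("kz", grid.T)):
        jumps = np.abs(np.diff(g, axis=0))  # (n-1, n): boundary i between rows i, i+1
        if not np.any(jumps > tol):
            continue
        per_boundary = jumps.max(axis=1)
        i = int(np.argmax(per_boundary))
        loc_axis = (i + 0.5) - c  # boundary midpoint on this axis
        # distance to center: closest point of the jumping part of the boundary
        js = np.flatnonzero(jumps[i] > tol) - c
        dist = float(np.min(np.hypot(loc_axis, js)))
        entries.append(
            {
                "axis": axis,
                "location": float(loc_axis),
                "jump": float(per_boundary[i]),
                "distance_to_center": dist,
                "center_critical": bool(dist < n / 8.0),
                "other_coord": float(js[np.argmin(np.abs(js))] if len(js) else 0.0),
            }
        )
    return entries


def _radial_report(plot: MotionSamplingPlot, tol: float, n_bins: int = 64) -> list[dict]:
    traj = plot.trajectory
    if traj.kind == "stack_of_stars":
        angles = traj.meta.get("angle")
        if angles is None:
            angles = np.rad2deg(
                np.arctan2(traj.coords[:, -1, 1], traj.coords[:, -1, 0])
            ) % 180.0
        period = 180.0
    else:  # kooshball: bin spokes by azimuth
        angles = traj.meta.get("azimuth_deg")
        if angles is None:
            angles = np.rad2deg(np.arctan2(traj.coords[:, -1, 1], traj.coords[:, -1, 0])) % 360.0
        period = 360.0
        bins = np.floor(angles / (period / n_bins)).astype(int)
        angles = bins * (period / n_bins)
    # mean value per distinct angle (stack-of-stars: over its kz readouts)
    uniq, inv = np.unique(np.round(angles, 9), return_inverse=True)
    means = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(means, inv, plot.values)
    np.add.at(counts, inv, 1.0)
    means /= counts
    if len(uniq) < 2:
        return []
    entries = []
    # adjacent in angle, including the wrap boundary (the last spoke is
    # spatially adjacent to the first, mirrored through the origin)
    jumps = np.abs(np.diff(means))
    boundaries = (uniq[:-1] + uniq[1:]) / 2.0
    wrap_jump = abs(means[0] - means[-1])
    wrap_boundary = ((uniq[-1] + uniq[0] + period) / 2.0) % period
    all_jumps = np.append(jumps, wrap_jump)
    all_bounds = np.append(boundaries, wrap_boundary)
    i = int(np.argmax(all_jumps))
    if all_jumps[i] > tol:
        entries.append(
            {
                "axis": "angle",
                "location": float(all_bounds[i]),
                "jump": float(all_jumps[i]),
                "distance_to_center": 0.0,
                "center_critical": True,  # full spokes pass through DC
            }
        )
    return entries


def discontinuity_report(plot: MotionSamplingPlot, tol: float = 1e-9) -> list[dict]:
    """Largest pose jumps between spatially adjacent samples.

    Cartesian: per phase-encode axis, the boundary between adjacent integer
    coordinates with the largest |value| jump.  Radial: per angle-sorted
    adjacent spokes (including the 0/180 or 0/360 wrap boundary).  Jumps whose
    distance to the k-space center is below n/8 are flagged center-critical;
    radial discontinuities run along full spokes through DC and are always
    center-critical.  A constant plot yields an empty report.
    """
    if plot.trajectory.n_readouts == 0:
        raise ValueError("empty motion-sampling plot")
    if plot.trajectory.kind == "cartesian":
        return _cartesian_report(plot, tol)
    return _radial_report(plot, tol)


def save_msplot_h5(plot: MotionSamplingPlot, path) -> None:
    """Serialize plot data (coordinates + per-sample values) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coordinates", data=plot.coords)
        f.create_dataset("values", data=plot.sample_values())
        f.create_dataset("readout_values", data=plot.values)
        f.attrs["parameter"] = plot.parameter
        f.attrs["reference"] = plot.reference
        f.attrs["kind"] = plot.trajectory.kind
        f.attrs["ordering"] = plot.trajectory.ordering
        f.attrs["n"] = plot.trajectory.n
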