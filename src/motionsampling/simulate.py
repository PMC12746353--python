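"""Synthesis of rigid-motion-corrupted k-space data.

The acquisition model: the motion track is quantized to a small number of
motion frames (100 by default); readouts are grouped by frame; for each
occupied frame the phantom is posed once (rotation by cubic resampling about
the grid center) and its spectrum is sampled at exactly that frame's readout
coordinates.  The translation component -- including the translation induced
by an off-center rotation point -- is applied exactly as a unit-magnitude
linear phase on the sampled coordinates, so pure translations never touch the
interpolator.  Outputs are concatenated in acquisition order.

One pose per readout (motion during the signal readout is ignored), a single
homogeneous receive channel, and no noise by default (a complex white-noise
hook with configurable SNR exists but is off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .motion import MotionTrack, discretize_states, state_labels
from .nufft import dft3_direct, fft3_centered, nufft_forward
from .phantom import RigidPose, effective_translation, rotate_about_grid_center
from .trajectory import Trajectory

DEFAULT_N_STATES = 100


@dataclass
class KSpaceData:
    """Complex k-space samples aligned one-to-one with trajectory coordinates.

    ``samples`` has the trajectory's (n_readouts, samples_per_readout) shape.
    ``n_transforms`` records how many distinct phantom transformations the
    simulation performed (= number of occupied motion states).
    """

    samples: np.ndarray
    trajectory: Trajectory
    track: MotionTrack | None = None
    n_transforms: int = 1

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def flat_samples(self) -> np.ndarray:
        return self.samples.reshape(-1)


def _coords_radius_ok(coords: np.ndarray, n: int) -> bool:
    rmax = (n / 2.0) * math.sqrt(3.0) * (1.0 + 1e-9)
    return bool(np.all(np.linalg.norm(np.asarray(coords, float).reshape(-1, 3), axis=-1) <= rmax))


def _is_integer_grid(coords: np.ndarray, n: int) -> bool:
    c = np.asarray(coords, float).reshape(-1, 3)
    on_grid = np.all(np.abs(c - np.round(c)) < 1e-9)
    return bool(on_grid and c.min() >= -(n // 2) - 1e-9 and c.max() <= n - 1 - n // 2 + 1e-9)


def forward_model(vol: np.ndarray, coords: np.ndarray, method: str = "auto") -> np.ndarray:
    """Sample the centered spectrum of ``vol`` at k-space ``coords``.

    ``F(k) = sum_r vol[r] exp(-2 pi i k . r / n)`` with r the voxel offset
    from the grid center.  ``method`` selects the evaluation path: ``"auto"``
    gathers from the FFT when all coordinates are exact integers (Cartesian)
    and uses the gridding NUFFT otherwise; ``"nufft"``, ``"fft"`` and
    ``"direct"`` (brute-force reference) force a path.
    """
    n = vol.shape[0]
    coords = np.asarray(coords, float)
    flat = coords.reshape(-1, 3)
    if not _coords_radius_ok(flat, n):
        raise ValueError(
            "k-space coordinates outside the supported ball of radius (n/2)*sqrt(3)"
        )
    if method == "auto":
        method = "fft" if _is_integer_grid(flat, n) else "nufft"
    if method == "fft":
        if not _is_integer_grid(flat, n):
            raise ValueError("fft path requires exact integer grid coordinates")
        spec = fft3_centered(vol)
        idx = np.round(flat).astype(int) + n // 2
        out = spec[idx[:, 0], idx[:, 1], idx[:, 2]]
    elif method == "nufft":
        out = nufft_forward(vol, flat)
    elif method == "direct":
        out = dft3_direct(vol, flat)
    else:
        raise ValueError(f"unknown forward method {method!r}")
    return out.reshape(coords.shape[:-1])


def _translation_phase(coords: np.ndarray, t_vox: np.ndarray, n: int) -> np.ndarray:
    return np.exp(-2j * np.pi * (coords.reshape(-1, 3) @ np.asarray(t_vox, float)) / n)


def simulate_motion_corrupted(
    phantom: np.ndarray,
    trajectory: Trajectory,
    track: MotionTrack,
    n_states: int = DEFAULT_N_STATES,
    interpolation: str = "cubic",
    method: str = "auto",
    noise_snr: float | None = None,
    seed: int = 0,
) -> KSpaceData:
    """Simulate the motion-corrupted acquisition of ``phantom``.

    The track is discretized to at most ``n_states`` motion frames; the
    phantom is transformed once per occupied frame and its spectrum sampled at
    that frame's readout coordinates.  ``noise_snr`` optionally adds complex
    white noise scaled so that mean |signal| / noise-sigma equals the given
    value (defaults to noiseless).
    """
    if track.n_readouts != trajectory.n_readouts:
        raise ValueError(
            f"track length {track.n_readouts} does not match "
            f"trajectory readout count {trajectory.n_readouts}"
        )
    n = phantom.shape[0]
    dtrack = discretize_states(track, n_states)
    labels = state_labels(dtrack)
    samples = np.empty(trajectory.coords.shape[:2], complex)
    n_transforms = 0
    for lab in np.unique(labels):
        sel = labels == lab
        pose = dtrack.pose(int(np.flatnonzero(sel)[0]))
        rotated = rotate_about_grid_center(phantom, pose, interpolation)
        n_transforms += 1
        coords = trajectory.coords[sel].reshape(-1, 3)
        vals = forward_model(rotated, coords, method=method)
        t_eff = effective_translation(pose, phantom.shape)
        if np.any(t_eff != 0.0):
            vals = vals * _translation_phase(coords, t_eff, n)
        samples[sel] = vals.reshape(sel.sum(), -1)
    if noise_snr is not None:
        rng = np.random.default_rng(seed)
        sigma = np.mean(np.abs(samples)) / noise_snr
        samples = samples + sigma * (
            rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        ) / math.sqrt(2.0)
    return KSpaceData(samples, trajectory, track, n_transforms)


def save_kspace_h5(kdata: KSpaceData, path) -> None:
    """Serialize k-space data (samples + coordinates + track) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=kdata.samples)
        f.create_dataset("coordinates", data=kdata.trajectory.coords)
        f.create_dataset("order_index", data=np.arange(kdata.trajectory.n_readouts))
        f.attrs["kind"] = kdata.trajectory.kind
        f.attrs["ordering"] = kdata.trajectory.ordering
        f.attrs["n"] = kdata.trajectory.n
        f.attrs["n_transforms"] = kdata.n_transforms
        if kdata.track is not None:
            f.create_dataset("track/rotations", data=kdata.track.rotations)
            f.create_dataset("track/translations", data=kdata.track.translations)
            f.attrs["track_reference"] = kdata.track.reference


def load_kspace_h5(path) -> KSpaceData:
    import h5py

    from .trajectory import Trajectory

    with h5py.File(path, "r") as f:
        samples = f["samples"][...]
        coords = f["coordinates"][...]
        traj = Trajectory(coords, f.attrs["kind"], f.attrs["ordering"], int(f.attrs["n"]))
        track = None
        if "track" in f:
            track = MotionTrack(
                f["track/rotations"][...],
                f["track/translations"][...],
                reference=f.attrs.get("track_reference", "absolute"),
            )
        return KSpaceData(samples, traj, track, int(f.attrs.get("n_transforms", 1)))
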