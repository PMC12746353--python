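"""Time-ordered 3D k-space sampling patterns.

Three trajectories are provided, each with a *smooth* (sequential sweep) and a
*non-smooth* (randomized / golden-angle) view ordering:

* ``cartesian`` - full ``n x n`` phase-encode grid, one kx readout line per TR;
* ``stack_of_stars`` - radial spokes in the kx-ky plane at Cartesian kz steps;
* ``kooshball`` - 3D radial spokes through the origin on a half-sphere.

k-space coordinates are in cycles/FOV on the integer Cartesian grid
``[-n/2, n/2 - 1]``.  Radial spokes are full spokes extended beyond the
Cartesian Nyquist radius -- by sqrt(2) (stack-of-stars, in plane) and sqrt(3)
(kooshball) -- so that their endpoints reach the corners of the corresponding
Cartesian grid.  Spoke counts follow the theoretical Nyquist limit
``ceil(n * pi / 2)`` (in-plane) and ``ceil(n**2 * pi / 2)`` (sphere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0

# Multidimensional golden means: with psi the real root of x**3 = x**2 + 1,
# the pair (1/psi**2, 1/psi) drives quasi-uniform incremental coverage of the
# (z, azimuth) cylinder and hence of the half-sphere.
_PSI = float(np.real(next(r for r in np.roots([1.0, -1.0, 0.0, -1.0]) if abs(np.imag(r)) < 1e-12)))
GOLDEN_MEANS: tuple[float, float] = (1.0 / _PSI**2, 1.0 / _PSI)


def tiny_golden_angle(level: int) -> float:
    """Tiny golden angle of the given level, in degrees.

    ``psi_N = 180 / (tau + N - 1)`` with ``tau`` the golden ratio; level 1 is
    the classic golden angle (111.246...deg), higher levels give smaller
    increments while retaining quasi-uniform angle coverage.
    """
    level = int(level)
    if level < 1:
        raise ValueError("tiny golden angle level must be >= 1")
    return 180.0 / (GOLDEN_RATIO + level - 1)


def nyquist_spokes(n: int, kind: str) -> int:
    """Number of spokes (or Cartesian readouts) at the theoretical Nyquist limit."""
    if kind == "cartesian":
        return int(n) ** 2
    if kind == "stack_of_stars":
        return math.ceil(n * math.pi / 2.0)
    if kind == "kooshball":
        return math.ceil(n**2 * math.pi / 2.0)
    raise ValueError(f"unknown trajectory kind {kind!r}")


@dataclass
class Trajectory:
    """A time-ordered set of readouts with exact k-space sample coordinates.

    ``coords`` has shape (n_readouts, samples_per_readout, 3); readout order
    along axis 0 is acquisition order (one readout per TR).  ``meta`` carries
    per-readout geometry (phase encodes, spoke angles/directions) used by the
    reconstruction and the discontinuity report.
    """

    coords: np.ndarray
    kind: str
    ordering: str
    n: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_readouts(self) -> int:
        return self.coords.shape[0]

    @property
    def samples_per_readout(self) -> int:
        return self.coords.shape[1]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0] * self.coords.shape[1]

    def flat_coords(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)


def _kgrid(n: int) -> np.ndarray:
    return np.arange(n, dtype=float) - n // 2


def cartesian_trajectory(n: int, ordering: str = "smooth", seed: int = 0) -> Trajectory:
    """Fully sampled Cartesian trajectory: one kx line per (ky, kz) pair.

    Smooth ordering is the nested loop with ky the slow (outer, low-to-high)
    and kz the fast (inner, low-to-high) phase encode.  Non-smooth ordering is
    a uniform shuffle of the same (ky, kz) set, reproducible from ``seed``.
    """
    n = int(n)
    if n < 2:
        raise ValueError("matrix size must be >= 2")
    k = _kgrid(n)
    ky, kz = np.meshgrid(k, k, indexing="ij")  # ky outer, kz inner
    ky, kz = ky.ravel(), kz.ravel()
    if ordering == "non_smooth":
        perm = np.random.default_rng(seed).permutation(n * n)
        ky, kz = ky[perm], kz[perm]
    elif ordering != "smooth":
        raise ValueError(f"unknown ordering {ordering!r}")
    kx = _kgrid(n)
    coords = np.empty((n * n, n, 3))
    coords[:, :, 0] = kx[None, :]
    coords[:, :, 1] = ky[:, None]
    coords[:, :, 2] = kz[:, None]
    return Trajectory(coords, "cartesian", ordering, n, seed, meta={"ky": ky, "kz": kz})


def _spoke_radii(n: int, extension: float) -> np.ndarray:
    """Sample radii of a full spoke: uniform spacing ~1 cycle/FOV, endpoints
    exactly at +/- (n/2) * extension.

    The count is rounded up to odd so every full spoke samples the k-space
    origin exactly -- the DC sample anchors the density-compensation weights
    and avoids a reconstruction pathology when all innermost samples sit a
    half-spacing off center.
    """
    kmax = (n / 2.0) * extension
    m = math.ceil(n * extension)
    if m % 2 == 0:
        m += 1
    return np.linspace(-kmax, kmax, m)


def stack_of_stars_trajectory(n: int, ordering: str = "smooth") -> Trajectory:
    """Full-spoke stack-of-stars: radial kx-ky spokes, Cartesian kz.

    Every kz at a given angle is sampled (low to high) before moving to the
    next spoke angle.  Smooth ordering sweeps uniformly spaced angles over
    [0, 180); non-smooth increments by the level-3 tiny golden angle mod 180.
    """
    n = int(n)
    if n < 2:
        raise ValueError("matrix size must be >= 2")
    n_sp = nyquist_spokes(n, "stack_of_stars")
    j = np.arange(n_sp)
    if ordering == "smooth":
        angles = j * (180.0 / n_sp)
    elif ordering == "non_smooth":
        angles = (j * tiny_golden_angle(3)) % 180.0
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    radii = _spoke_radii(n, math.sqrt(2.0))
    kz = _kgrid(n)
    a = np.deg2rad(angles)
    # readout order: spoke-major, kz-minor
    coords = np.empty((n_sp, n, len(radii), 3))
    coords[..., 0] = (radii[None, :] * np.cos(a)[:, None])[:, None, :]
    coords[..., 1] = (radii[None, :] * np.sin(a)[:, None])[:, None, :]
    coords[..., 2] = kz[None, :, None]
    coords = coords.reshape(n_sp * n, len(radii), 3)
    meta = {
        "angle": np.repeat(angles, n),
        "kz": np.tile(kz, n_sp),
        "n_spokes": n_sp,
        "radii": radii,
    }
    return Trajectory(coords, "stack_of_stars", ordering, n, None, meta=meta)


def _archimedean_half_sphere(m: int) -> np.ndarray:
    """Unit directions along an equal-area spiral sweeping the half-sphere
    from the +z pole to the equator (acquisition order).

    The sweep direction only decides which pole anchors the ordering (and
    hence the orientation of ordering-dependent artifacts); the polar cap is
    acquired at the start of the scan.
    """
    z = 1.0 - np.arange(m) / (m - 1.0)
    phi = np.zeros(m)
    # azimuth increment keeps arc length between successive points uniform for
    # an equal-area point density (Saff-Kuijlaars constant, full-sphere
    # equivalent density 2m)
    c = 3.6 / math.sqrt(2.0 * m)
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    for i in range(1, m):
        phi[i] = phi[i - 1] + (c / s[i] if s[i] > 0 else 0.0)
    phi %= 2.0 * math.pi
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=-1)


def _golden_means_half_sphere(m: int) -> np.ndarray:
    """Quasi-random half-sphere directions from the 2D golden-means increments."""
    i = np.arange(m)
    z = np.mod(i * GOLDEN_MEANS[0], 1.0)
    phi = 2.0 * math.pi * np.mod(i * GOLDEN_MEANS[1], 1.0)
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=-1)


def kooshball_trajectory(n: int, ordering: str = "smooth") -> Trajectory:
    """Full-spoke 3D radial (kooshball) trajectory, one spoke per TR.

    Spoke directions lie on the upper half-sphere; smooth ordering follows an
    equal-area Archimedean spiral from the pole to the equator, non-smooth
    ordering follows the multidimensional golden means.
    """
    n = int(n)
    if n < 2:
        raise ValueError("matrix size must be >= 2")
    m_sp = nyquist_spokes(n, "kooshball")
    if ordering == "smooth":
        dirs = _archimedean_half_sphere(m_sp)
    elif ordering == "non_smooth":
        dirs = _golden_means_half_sphere(m_sp)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    radii = _spoke_radii(n, math.sqrt(3.0))
    coords = radii[None, :, None] * dirs[:, None, :]
    meta = {
        "direction": dirs,
        "azimuth_deg": np.rad2deg(np.arctan2(dirs[:, 1], dirs[:, 0])) % 360.0,
        "polar_deg": np.rad2deg(np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))),
        "n_spokes": m_sp,
        "radii": radii,
    }
    return Trajectory(coords, "kooshball", ordering, n, None, meta=meta)


_MAKERS = {
    "cartesian": cartesian_trajectory,
    "stack_of_stars": stack_of_stars_trajectory,
    "kooshball": kooshball_trajectory,
}


def make_trajectory(kind: str, n: int, ordering: str = "smooth", seed: int = 0) -> Trajectory:
    """Dispatch to one of the three trajectory generators by name."""
    aliases = {"sos": "stack_of_stars"}
    kind = aliases.get(kind, kind)
    if kind not in _MAKERS:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    if kind == "cartesian":
        return cartesian_trajectory(n, ordering, seed)
    return _MAKERS[kind](n, ordering)


def save_trajectory_h5(traj: Trajectory, path) -> None:
    """Serialize a trajectory to HDF5 (coordinates + acquisition order)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coordinates", data=traj.coords)
        f.create_dataset("order_index", data=np.arange(traj.n_readouts))
        f.attrs["kind"] = traj.kind
        f.attrs["ordering"] = traj.ordering
        f.attrs["n"] = traj.n
        if traj.seed is not None:
            f.attrs["seed"] = traj.seed


def load_trajectory_h5(path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        coords = f["coordinates"][...]
        kind = f.attrs["kind"]
        ordering = f.attrs["ordering"]
        n = int(f.attrs["n"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    return Trajectory(coords, kind, ordering, n, seed)
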