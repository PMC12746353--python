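"""3D Shepp-Logan phantom and rigid-body transformation of volumes.

The digital head phantom is the classic ten-ellipsoid 3D Shepp-Logan object
(Kak-Slaney geometry with the "modified" high-contrast intensities).  Each
ellipsoid is an indicator function in normalized coordinates [-1, 1]; the
phantom value at a point is the intensity-weighted sum of the indicators.

Coordinate conventions used throughout the package:

* array axes (0, 1, 2) correspond to physical x (left-right),
  y (anterior-posterior) and z (superior-inferior);
* the physical origin sits at voxel index ``n // 2`` on each axis (the FFT
  center convention), and normalized phantom coordinates are
  ``(index - n // 2) / (n / 2)``;
* rotations are extrinsic about the fixed scanner axes, applied in the order
  yaw after roll after pitch (``R = Rz @ Ry @ Rx``), right-hand rule, degrees.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class Ellipsoid:
    """One constituent ellipsoid of an analytic phantom.

    Parameters are in normalized coordinates: ``center`` and ``semi_axes``
    live in [-1, 1]; ``euler_angles`` are degrees about the (z, y, x) axes
    applied in that (intrinsic) order; ``intensity`` is the additive signal
    contributed inside the ellipsoid.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    euler_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.semi_axes):
            raise ValueError("ellipsoid semi-axes must be strictly positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of ``points`` (shape (..., 3), normalized)."""
        rot = Rotation.from_euler("zyx", self.euler_angles, degrees=True)
        local = (np.asarray(points, float) - np.asarray(self.center)) @ rot.as_matrix()
        return np.sum((local / np.asarray(self.semi_axes)) ** 2, axis=-1) <= 1.0


#: Modified 3D Shepp-Logan phantom: (intensity, semi-axes a/b/c, center, z-angle).
#: The z-rotation is about the superior-inferior axis (the only one the
#: classical table uses).
SHEPP_LOGAN_3D: tuple[Ellipsoid, ...] = tuple(
    Ellipsoid(center=(x0, y0, z0), semi_axes=(a, b, c), euler_angles=(phi, 0.0, 0.0), intensity=A)
    for (A, a, b, c, x0, y0, z0, phi) in [
        (1.0, 0.6900, 0.9200, 0.810, 0.0, 0.0, 0.0, 0.0),
        (-0.8, 0.6624, 0.8740, 0.780, 0.0, -0.0184, 0.0, 0.0),
        (-0.2, 0.1100, 0.3100, 0.220, 0.22, 0.0, 0.0, -18.0),
        (-0.2, 0.1600, 0.4100, 0.280, -0.22, 0.0, 0.0, 18.0),
        (0.1, 0.2100, 0.2500, 0.410, 0.0, 0.35, -0.15, 0.0),
        (0.1, 0.0460, 0.0460, 0.050, 0.0, 0.10, 0.25, 0.0),
        (0.1, 0.0460, 0.0460, 0.050, 0.0, -0.10, 0.25, 0.0),
        (0.1, 0.0460, 0.0230, 0.050, -0.08, -0.605, 0.0, 0.0),
        (0.1, 0.0230, 0.0230, 0.020, 0.0, -0.606, 0.0, 0.0),
        (0.1, 0.0230, 0.0460, 0.020, 0.06, -0.605, 0.0, 0.0),
    ]
)


def phantom_intensity(points: np.ndarray, ellipsoids=SHEPP_LOGAN_3D) -> np.ndarray:
    """Analytic phantom value at normalized coordinates ``points`` (..., 3)."""
    points = np.asarray(points, float)
    out = np.zeros(points.shape[:-1])
    for e in ellipsoids:
        out += e.intensity * e.contains(points)
    return out


def make_shepp_logan_3d(n: int, ellipsoids=SHEPP_LOGAN_3D) -> np.ndarray:
    """Rasterize the 3D Shepp-Logan phantom on an ``n**3`` voxel grid.

    Voxel values are the analytic ellipsoid-indicator sum evaluated at voxel
    centers; voxels outside the outer (skull) ellipsoid are exactly zero.
    """
    n = int(n)
    if n < 8:
        raise ValueError(f"matrix size n={n} too small to resolve the phantom (need n >= 8)")
    c = n // 2
    ax = (np.arange(n) - c) / (n / 2.0)
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
    return phantom_intensity(grid, ellipsoids)


def ellipsoid_table_to_csv(path, ellipsoids=SHEPP_LOGAN_3D) -> None:
    """Dump the phantom parameterization as CSV (one row per ellipsoid)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["intensity", "a", "b", "c", "x0", "y0", "z0", "phi_deg", "theta_deg", "psi_deg"])
        for e in ellipsoids:
            w.writerow([e.intensity, *e.semi_axes, *e.center, *e.euler_angles])


@dataclass(frozen=True)
class RigidPose:
    """Rigid-body pose: rotations (pitch, roll, yaw) in degrees about the
    physical x, y, z axes and translations in voxel units.

    The world map is ``x' = R (x - c) + c + t`` where ``c`` is the center of
    rotation (``None`` means the grid center) and ``R = Rz(yaw) @ Ry(roll) @
    Rx(pitch)`` (extrinsic, right-handed).
    """

    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_of_rotation: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        vals = [*self.rotations, *self.translations]
        if self.center_of_rotation is not None:
            vals += list(self.center_of_rotation)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite rigid pose parameters")

    @property
    def pitch(self) -> float:
        return self.rotations[0]

    @property
    def roll(self) -> float:
        return self.rotations[1]

    @property
    def yaw(self) -> float:
        return self.rotations[2]

    def rotation_matrix(self) -> np.ndarray:
        """3x3 rotation matrix ``Rz(yaw) @ Ry(roll) @ Rx(pitch)``."""
        return Rotation.from_euler("xyz", self.rotations, degrees=True).as_matrix()

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(
            np.all(np.abs(self.rotations) <= tol) and np.all(np.abs(self.translations) <= tol)
        )

    def inverse(self) -> "RigidPose":
        """Pose undoing this one (same center of rotation)."""
        rot = Rotation.from_euler("xyz", self.rotations, degrees=True)
        inv = rot.inv()
        # x = R^-1 (x' - c - t) + c, i.e. rotation R^-1 and translation -R^-1 t
        t_inv = -(inv.as_matrix() @ np.asarray(self.translations))
        angles = inv.as_euler("xyz", degrees=True)
        return RigidPose(tuple(angles), tuple(t_inv), self.center_of_rotation)


def _resolve_center(vol_shape, center) -> np.ndarray:
    if center is None:
        return np.array([s // 2 for s in vol_shape], float)
    return np.asarray(center, float)


def effective_translation(pose: RigidPose, vol_shape) -> np.ndarray:
    """Translation (voxels) equivalent to ``pose`` once its rotation is
    re-expressed about the grid center: ``t_eff = (I - R)(c_rot - c_grid) + t``.
    """
    R = pose.rotation_matrix()
    c_grid = np.array([s // 2 for s in vol_shape], float)
    d = _resolve_center(vol_shape, pose.center_of_rotation) - c_grid
    return (np.eye(3) - R) @ d + np.asarray(pose.translations, float)


_ORDERS = {"linear": 1, "cubic": 3}


def apply_rigid_transform(vol: np.ndarray, pose: RigidPose, interpolation: str = "cubic") -> np.ndarray:
    """Resample ``vol`` under the rigid world map of ``pose``.

    Values needed from outside the source support fill with zero.  Cubic
    spline interpolation is the default; ``"linear"`` trades accuracy for
    speed.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}, got {interpolation!r}")
    if pose.is_identity():
        return np.array(vol, copy=True)
    R = pose.rotation_matrix()
    c = _resolve_center(vol.shape, pose.center_of_rotation)
    t = np.asarray(pose.translations, float)
    # ndimage maps output index o to input index  M @ o + offset
    M = R.T
    offset = c - M @ (c + t)
    return ndimage.affine_transform(
        vol, M, offset=offset, order=_ORDERS[interpolation], mode="constant", cval=0.0,
        prefilter=True,
    )


def rotate_about_grid_center(vol: np.ndarray, pose: RigidPose, interpolation: str = "cubic") -> np.ndarray:
    """Apply only the rotation part of ``pose``, about the grid center.

    The simulator uses this together with :func:`effective_translation`, which
    it applies exactly as a linear phase in k-space instead of interpolating a
    sub-voxel shift.
    """
    rot_only = RigidPose(pose.rotations, (0.0, 0.0, 0.0), None)
    if rot_only.is_identity():
        return np.array(vol, copy=True)
    return apply_rigid_transform(vol, rot_only, interpolation)
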