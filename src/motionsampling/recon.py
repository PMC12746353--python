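"""Image reconstruction from (corrupted) k-space and error metrics.

Cartesian data are regridded onto the integer grid and inverted with a single
inverse FFT (exact round trip for fully sampled data).  Radial data are
reconstructed by density-compensated adjoint gridding: an analytic ramp
(|k| in-plane for stack-of-stars, |k|**2 for kooshball) expressed in
grid-cell units, with the DC sample weighted by the innermost annulus volume.
Spoke samples extended past the Cartesian Nyquist cube are excluded from the
adjoint (their contributions would wrap onto aliased grid frequencies and
over-weight them).

Artifact severity throughout the package is quantified by the NRMSE of
magnitude images, ``||x - ref||_2 / ||ref||_2``.
"""

from __future__ import annotations

import math

import numpy as np

from .nufft import ifft3_centered, nufft_adjoint
from .simulate import KSpaceData


def nrmse(vol: np.ndarray, ref: np.ndarray) -> float:
    """Normalized RMS error between magnitude images."""
    vol = np.abs(np.asarray(vol))
    ref = np.abs(np.asarray(ref))
    if vol.shape != ref.shape:
        raise ValueError(f"shape mismatch: {vol.shape} vs {ref.shape}")
    denom = np.linalg.norm(ref)
    if denom == 0:
        raise ValueError("reference volume has zero norm")
    return float(np.linalg.norm(vol - ref) / denom)


def recon_cartesian(kdata: KSpaceData) -> np.ndarray:
    """Inverse FFT of fully sampled Cartesian data (complex image)."""
    traj = kdata.trajectory
    if traj.kind != "cartesian":
        raise ValueError(f"recon_cartesian needs a cartesian trajectory, got {traj.kind!r}")
    n = traj.n
    c = n // 2
    ky = np.round(traj.coords[:, 0, 1]).astype(int) + c
    kz = np.round(traj.coords[:, 0, 2]).astype(int) + c
    counts = np.zeros((n, n), int)
    np.add.at(counts, (ky, kz), 1)
    if not np.all(counts == 1):
        raise ValueError("incomplete or duplicated Cartesian phase-encode grid")
    kx = np.round(traj.coords[0, :, 0]).astype(int) + c
    if not np.array_equal(kx, np.arange(n)):
        raise ValueError("Cartesian readout lines must span the full kx grid in order")
    spec = np.zeros((n, n, n), complex)
    spec[:, ky, kz] = kdata.samples.T
    return ifft3_centered(spec)


def density_weights(traj) -> np.ndarray:
    """Analytic density-compensation weights in grid-cell units, shaped like
    the trajectory's (n_readouts, samples_per_readout) sample array.

    Samples whose coordinates leave the Cartesian Nyquist cube (any component
    beyond n/2) get zero weight.
    """
    n = traj.n
    m = traj.samples_per_readout
    if traj.kind == "stack_of_stars":
        n_spokes = traj.meta.get("n_spokes", traj.n_readouts // n)
        kmax = (n / 2.0) * math.sqrt(2.0)
        delta = 2.0 * kmax / (m - 1)
        r = np.abs(np.linspace(-kmax, kmax, m))
        w_line = (math.pi / n_spokes) * delta * r
        w_line[r < delta / 2.0] = math.pi * (delta / 2.0) ** 2 / n_spokes
        w = np.broadcast_to(w_line, (traj.n_readouts, m)).copy()
    elif traj.kind == "kooshball":
        n_spokes = traj.n_readouts
        kmax = (n / 2.0) * math.sqrt(3.0)
        delta = 2.0 * kmax / (m - 1)
        r = np.abs(np.linspace(-kmax, kmax, m))
        w_line = (2.0 * math.pi / n_spokes) * delta * r**2
        w_line[r < delta / 2.0] = (4.0 * math.pi / 3.0) * (delta / 2.0) ** 3 / n_spokes
        w = np.broadcast_to(w_line, (traj.n_readouts, m)).copy()
    elif traj.kind == "cartesian":
        w = np.ones((traj.n_readouts, m))
    else:
        raise ValueError(f"unknown trajectory kind {traj.kind!r}")
    outside = np.any(np.abs(traj.coords) > n / 2.0 + 1e-9, axis=-1)
    w[outside] = 0.0
    return w


def recon_radial(kdata: KSpaceData) -> np.ndarray:
    """Density-compensated adjoint gridding of full-spoke radial data."""
    traj = kdata.trajectory
    if traj.kind not in ("stack_of_stars", "kooshball"):
        raise ValueError(f"recon_radial needs a radial trajectory, got {traj.kind!r}")
    w = density_weights(traj)
    img = nufft_adjoint(
        (w * kdata.samples).reshape(-1), traj.flat_coords(), traj.n
    )
    return img / float(traj.n) ** 3


def reconstruct(kdata: KSpaceData) -> np.ndarray:
    """Dispatch to the Cartesian or radial reconstruction by trajectory kind."""
    if kdata.trajectory.kind == "cartesian":
        return recon_cartesian(kdata)
    return recon_radial(kdata)
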