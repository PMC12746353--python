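"""Non-uniform discrete Fourier transform via Kaiser-Bessel gridding.

The forward (type-2) transform evaluates

    F(k) = sum_r  v[r] * exp(-2j * pi * k . r / n)

for arbitrary k in cycles/FOV, with r the voxel offset from the grid center
(index ``n // 2``).  On integer k this coincides with the centered FFT of the
volume.  The fast path deapodizes the image, zero-pads to a 2x oversampled
grid, FFTs, and interpolates the spectrum with a width-8 Kaiser-Bessel kernel
(Beatty shape parameter); the adjoint spreads samples onto the oversampled
grid with the same kernel.  Sample positions wrap modulo the oversampled grid,
which matches the n-periodicity of the discrete spectrum, so spoke extensions
past the Cartesian Nyquist radius are handled consistently.

A brute-force direct evaluation (:func:`dft3_direct`) is retained as the slow
exact reference path.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.fft import fftn, fftshift, ifftn, ifftshift
from scipy.special import i0 as bessel_i0

DEFAULT_OSF = 2.0
DEFAULT_WIDTH = 8
_TABLE_SIZE = 1 << 15


def kb_beta(width: int = DEFAULT_WIDTH, osf: float = DEFAULT_OSF) -> float:
    """Kaiser-Bessel shape parameter minimizing aliasing error (Beatty)."""
    return math.pi * math.sqrt((width / osf) ** 2 * (osf - 0.5) ** 2 - 0.8)


def _kb_table(width: int, beta: float) -> np.ndarray:
    """Kernel values sampled on [0, width/2] for linear-interp lookup,
    normalized to kb(0) = 1."""
    u = np.linspace(0.0, width / 2.0, _TABLE_SIZE)
    t = 2.0 * u / width
    vals = bessel_i0(beta * np.sqrt(np.clip(1.0 - t**2, 0.0, None))) / bessel_i0(beta)
    vals[t > 1.0] = 0.0
    return np.ascontiguousarray(vals)


def _apodization_1d(n: int, n_os: int, width: int, beta: float) -> np.ndarray:
    """Fourier transform of the (normalized) kernel at image offsets, per axis."""
    r = np.arange(n) - n // 2
    f = r / float(n_os)
    arg = beta**2 - (math.pi * width * f) ** 2
    # always positive for |f| <= 1/(2*osf) with the Beatty beta used here
    c = width * np.sinh(np.sqrt(arg)) / np.sqrt(arg)
    return c / float(bessel_i0(beta))


_table_cache: dict = {}


def _get_tables(width: int, osf: float):
    key = (width, round(osf, 6))
    if key not in _table_cache:
        beta = kb_beta(width, osf)
        _table_cache[key] = (beta, _kb_table(width, beta))
    return _table_cache[key]


@njit(cache=True)
def _kernel_weights(p: float, width: int, table: np.ndarray, offsets: np.ndarray, weights: np.ndarray) -> None:
    """Fill integer tap offsets and kernel weights for one coordinate."""
    half = width / 2.0
    scale = (table.shape[0] - 1) / half
    j0 = int(math.floor(p)) - width // 2 + 1
    for t in range(width):
        d = abs(p - (j0 + t))
        if d >= half:
            offsets[t] = j0 + t
            weights[t] = 0.0
        else:
            x = d * scale
            i = int(x)
            frac = x - i
            offsets[t] = j0 + t
            weights[t] = table[i] * (1.0 - frac) + table[i + 1] * frac


@njit(cache=True)
def _interp3(grid: np.ndarray, px: np.ndarray, py: np.ndarray, pz: np.ndarray,
             width: int, table: np.ndarray, out: np.ndarray) -> None:
    n_os = grid.shape[0]
    ox = np.empty(width, np.int64)
    oy = np.empty(width, np.int64)
    oz = np.empty(width, np.int64)
    wx = np.empty(width, np.float64)
    wy = np.empty(width, np.float64)
    wz = np.empty(width, np.float64)
    for s in range(px.shape[0]):
        _kernel_weights(px[s], width, table, ox, wx)
        _kernel_weights(py[s], width, table, oy, wy)
        _kernel_weights(pz[s], width, table, oz, wz)
        acc = 0.0 + 0.0j
        for a in range(width):
            ia = ox[a] % n_os
            for b in range(width):
                ib = oy[b] % n_os
                wab = wx[a] * wy[b]
                if wab == 0.0:
                    continue
                for c in range(width):
                    ic = oz[c] % n_os
                    acc += wab * wz[c] * grid[ia, ib, ic]
        out[s] = acc


@njit(cache=True)
def _spread3(grid: np.ndarray, px: np.ndarray, py: np.ndarray, pz: np.ndarray,
             vals: np.ndarray, width: int, table: np.ndarray) -> None:
    n_os = grid.shape[0]
    ox = np.empty(width, np.int64)
    oy = np.empty(width, np.int64)
    oz = np.empty(width, np.int64)
    wx = np.empty(width, np.float64)
    wy = np.empty(width, np.float64)
    wz = np.empty(width, np.float64)
    for s in range(px.shape[0]):
        _kernel_weights(px[s], width, table, ox, wx)
        _kernel_weights(py[s], width, table, oy, wy)
        _kernel_weights(pz[s], width, table, oz, wz)
        v = vals[s]
        for a in range(width):
            ia = ox[a] % n_os
            for b in range(width):
                ib = oy[b] % n_os
                wab = wx[a] * wy[b]
                if wab == 0.0:
                    continue
                for c in range(width):
                    ic = oz[c] % n_os
                    grid[ia, ib, ic] += wab * wz[c] * v


def _check_cube(vol: np.ndarray) -> int:
    if vol.ndim != 3 or len(set(vol.shape)) != 1:
        raise ValueError(f"expected a cubic 3D volume, got shape {vol.shape}")
    return vol.shape[0]


def _positions(coords: np.ndarray, osf: float, n_os: int):
    coords = np.ascontiguousarray(np.asarray(coords, float).reshape(-1, 3))
    p = coords * osf + n_os // 2
    return (np.ascontiguousarray(p[:, 0]), np.ascontiguousarray(p[:, 1]),
            np.ascontiguousarray(p[:, 2]))


def _pad_centered(x: np.ndarray, n_os: int) -> np.ndarray:
    n = x.shape[0]
    out = np.zeros((n_os, n_os, n_os), complex)
    s = slice(n_os // 2 - n // 2, n_os // 2 - n // 2 + n)
    out[s, s, s] = x
    return out


def nufft_forward(vol: np.ndarray, coords: np.ndarray,
                  osf: float = DEFAULT_OSF, width: int = DEFAULT_WIDTH) -> np.ndarray:
    """Type-2 NUFFT: sample the centered spectrum of ``vol`` at ``coords``
    (cycles/FOV).  Returns a flat complex array, one value per coordinate."""
    n = _check_cube(vol)
    n_os = int(round(osf * n))
    beta, table = _get_tables(width, osf)
    ap = _apodization_1d(n, n_os, width, beta)
    x = vol / (ap[:, None, None] * ap[None, :, None] * ap[None, None, :])
    grid = fftshift(fftn(ifftshift(_pad_centered(x, n_os))))
    grid = np.ascontiguousarray(grid)
    px, py, pz = _positions(coords, osf, n_os)
    out = np.empty(px.shape[0], complex)
    _interp3(grid, px, py, pz, width, table, out)
    return out


def nufft_adjoint(samples: np.ndarray, coords: np.ndarray, n: int,
                  osf: float = DEFAULT_OSF, width: int = DEFAULT_WIDTH) -> np.ndarray:
    """Adjoint of :func:`nufft_forward`: spread samples onto the oversampled
    grid, inverse-FFT, crop to ``n**3`` and deapodize."""
    n = int(n)
    n_os = int(round(osf * n))
    beta, table = _get_tables(width, osf)
    px, py, pz = _positions(coords, osf, n_os)
    vals = np.ascontiguousarray(np.asarray(samples, complex).ravel())
    if vals.shape[0] != px.shape[0]:
        raise ValueError("samples and coords must have the same length")
    grid = np.zeros((n_os, n_os, n_os), complex)
    _spread3(grid, px, py, pz, vals, width, table)
    x = fftshift(ifftn(ifftshift(grid))) * float(n_os) ** 3
    s = slice(n_os // 2 - n // 2, n_os // 2 - n // 2 + n)
    x = x[s, s, s]
    ap = _apodization_1d(n, n_os, width, beta)
    return x / (ap[:, None, None] * ap[None, :, None] * ap[None, None, :])


def dft3_direct(vol: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force direct evaluation of the same sum (slow exact reference)."""
    n = _check_cube(vol)
    c = n // 2
    r = np.arange(n) - c
    coords = np.asarray(coords, float).reshape(-1, 3)
    # separable phase factors keep this O(P * 3n) in memory
    px = np.exp(-2j * np.pi * np.outer(coords[:, 0], r) / n)
    py = np.exp(-2j * np.pi * np.outer(coords[:, 1], r) / n)
    pz = np.exp(-2j * np.pi * np.outer(coords[:, 2], r) / n)
    out = np.empty(coords.shape[0], complex)
    for s in range(coords.shape[0]):
        out[s] = np.einsum("ijk,i,j,k->", vol, px[s], py[s], pz[s], optimize=True)
    return out


def fft3_centered(vol: np.ndarray) -> np.ndarray:
    """Centered FFT: spectrum value at integer k equals the type-2 sum."""
    return fftshift(fftn(ifftshift(vol)))


def ifft3_centered(spec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft3_centered` (round trip is exact)."""
    return fftshift(ifftn(ifftshift(spec)))
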