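"""Volume import/export helpers (NIfTI) and tri-planar mosaic snapshots."""

from __future__ import annotations

import numpy as np


def save_volume_nifti(vol: np.ndarray, path, voxel_size: float = 1.0) -> None:
    """Write a (real or magnitude) volume as NIfTI with an isotropic affine."""
    import nibabel as nib

    data = np.asarray(vol)
    if np.iscomplexobj(data):
        data = np.abs(data)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))


def load_volume_nifti(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())


def save_triplanar_png(vol: np.ndarray, path, title: str | None = None, dpi: int = 110):
    """Center axial / sagittal / coronal slices side by side.

    Motion artifacts are directional; a single plane can hide them, so
    snapshots always show all three.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mag = np.abs(np.asarray(vol))
    c = [s // 2 for s in mag.shape]
    slices = [
        (mag[:, :, c[2]].T, "axial (x-y)"),
        (mag[c[0], :, :].T, "sagittal (y-z)"),
        (mag[:, c[1], :].T, "coronal (x-z)"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(10.5, 3.8))
    vmax = float(np.percentile(mag, 99.8)) or 1.0
    for ax, (sl, name) in zip(axes, slices):
        ax.imshow(sl, cmap="gray", origin="lower", vmin=0.0, vmax=vmax)
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
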