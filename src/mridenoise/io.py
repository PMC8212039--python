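"""Reading and writing complex MRI volumes (HDF5, NIfTI, PNG previews)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "write_complex_volume",
    "read_complex_volume",
    "write_nifti_magnitude",
    "write_png_preview",
]


def write_complex_volume(path, volume: np.ndarray, dataset: str = "image") -> None:
    """Write a (slices, H, W) complex array to an HDF5 dataset."""
    vol = np.asarray(volume, dtype=np.complex128)
    if vol.ndim != 3:
        raise ValueError(f"expected (slices, H, W) volume, got shape {vol.shape}")
    with h5py.File(path, "w") as fh:
        fh.create_dataset(dataset, data=vol)


def read_complex_volume(path, dataset: str | None = None) -> np.ndarray:
    """Read a complex volume; tries 'kspace' (raw single-coil layout) then 'image'."""
    with h5py.File(path, "r") as fh:
        if dataset is None:
            for name in ("kspace", "image"):
                if name in fh:
                    dataset = name
                    break
            else:
                raise KeyError(f"no 'kspace' or 'image' dataset in {path}")
        return np.asarray(fh[dataset], dtype=np.complex128)


def write_nifti_magnitude(path, volume: np.ndarray) -> None:
    """Export a magnitude volume as NIfTI (identity affine, index coordinates)."""
    import nibabel as nib

    mag = np.abs(np.asarray(volume))
    nib.save(nib.Nifti1Image(mag.astype(np.float32), np.eye(4)), str(path))


def write_png_preview(path, magnitude_2d: np.ndarray) -> None:
    """Write a grayscale PNG of a single magnitude slice."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(magnitude_2d, dtype=np.float64)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(arr, cmap="gray", interpolation="nearest")
    ax.axis("off")
    fig.savefig(Path(path), bbox_inches="tight", dpi=120)
    plt.close(fig)
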