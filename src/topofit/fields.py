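"""Scalar fields: the 2D/3D probability maps and images the whole package operates on.

A scalar field is simply a ``numpy.ndarray`` of dimension 2 or 3 whose entries
lie in [0, 1].  Pixel ``(i, j)`` is identified with the closed unit square
``[i, i+1] x [j, j+1]`` (analogously for voxels), which fixes the geometry used
by the cubical-complex machinery in :mod:`topofit.cubical`.
"""

from __future__ import annotations

import os

import numpy as np

__all__ = [
    "validate_field",
    "normalize01",
    "load_field",
    "save_field",
]


def validate_field(values: np.ndarray, *, name: str = "field") -> np.ndarray:
    """Validate a scalar field and return it as a float64 array.

    Raises ``ValueError`` if the array is empty, not 2- or 3-dimensional,
    contains non-finite entries, or has values outside [0, 1].
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise ValueError(f"{name} must be 2- or 3-dimensional, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(
            f"{name} values must lie in [0, 1]; observed range "
            f"[{arr.min():.4g}, {arr.max():.4g}] (use normalize01 first)"
        )
    return arr


def normalize01(values: np.ndarray) -> np.ndarray:
    """Min-max rescale an array to [0, 1]; a constant array maps to all zeros."""
    arr = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot normalise non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def load_field(path: str | os.PathLike) -> np.ndarray:
    """Read a greyscale image (PNG/TIFF) or volume (NIfTI) as a [0,1] field.

    2D images are converted to greyscale by channel averaging if needed and
    min-max rescaled; NIfTI volumes are rescaled likewise.
    """
    p = str(path)
    ext = p.lower()
    if ext.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(p).dataobj).astype(np.float64)
        if vol.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI volume, got shape {vol.shape}")
        return normalize01(vol)
    import imageio.v3 as iio

    img = np.asarray(iio.imread(p), dtype=np.float64)
    if img.ndim == 3:  # RGB(A) -> grey
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D greyscale image, got shape {img.shape}")
    return normalize01(img)


def save_field(path: str | os.PathLike, values: np.ndarray) -> None:
    """Write a field to PNG/TIFF (2D, 8-bit for PNG) or NIfTI (3D)."""
    arr = validate_field(values)
    p = str(path)
    if p.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4)), p)
        return
    if arr.ndim != 2:
        raise ValueError("only NIfTI output is supported for 3D fields")
    import imageio.v3 as iio

    if p.lower().endswith((".tif", ".tiff")):
        iio.imwrite(p, arr.astype(np.float32))
    else:
        iio.imwrite(p, np.round(arr * 255).astype(np.uint8))
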