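"""Image reading/writing and tabular output helpers."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import rescale

__all__ = ["read_image", "write_image", "write_label_image", "read_label_image"]

# Rec.601 luminance weights for RGB collapse
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path: str | Path, resize_factor: float = 1.0) -> np.ndarray:
    """Read TIFF/PNG/JPEG as a float64 grayscale image on [0, 255].

    RGB(A) is collapsed to Rec.601 luminance; 8-bit input keeps its pixel
    values exactly, 16-bit is scaled by 255/65535, floats are assumed to be
    on [0, 1] (scaled up) or already on [0, 255].  ``resize_factor`` < 1
    downscales with anti-aliasing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3].astype(float) @ _LUMA
        else:
            arr = arr[..., 0].astype(float)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")

    if arr.dtype == np.uint8 or arr.dtype == float or arr.dtype == np.float64:
        arr = arr.astype(float)
        if np.issubdtype(np.asarray(arr).dtype, np.floating) and arr.max() <= 1.0:
            arr = arr * 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) * (255.0 / 65535.0)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if arr.max() > 255:
            arr = arr / arr.max() * 255.0
    elif np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(float)
        if arr.max() <= 1.0:
            arr = arr * 255.0
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype} in {path}")

    if not (0 < resize_factor <= 1):
        raise ValueError("resize_factor must be in (0, 1]")
    if resize_factor < 1.0:
        arr = rescale(arr / 255.0, resize_factor, anti_aliasing=True,
                      preserve_range=False) * 255.0
    return np.clip(arr, 0.0, 255.0)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 255] float image as 8-bit TIFF or PNG by extension."""
    path = Path(path)
    out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def write_label_image(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label image as 16-bit TIFF."""
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(int)
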