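"""Grayscale image I/O.

All images in this package are 2-D uint8 arrays (row-major, origin top-left,
(row, col) indexing). Binary masks are boolean arrays, serialized as 0/255
8-bit images.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio

__all__ = ["read_image", "write_image", "as_gray_u8", "as_mask"]

# ITU-R BT.601 luma weights, the convention PIL's "L" mode uses
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray_u8(arr: np.ndarray) -> np.ndarray:
    """Coerce an array to a valid 2-D uint8 grayscale image."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {a.shape}")
    if a.dtype == np.uint8:
        return a
    if np.issubdtype(a.dtype, np.floating):
        a = np.rint(a)
    if np.any(a < 0) or np.any(a > 255):
        raise ValueError("intensities outside [0, 255]")
    return a.astype(np.uint8)


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Coerce an array to a 2-D boolean mask."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"expected a non-empty 2-D mask, got shape {a.shape}")
    return a.astype(bool)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as 2-D uint8 grayscale.

    Color inputs are converted to single-channel luminance (BT.601 weights);
    16-bit inputs are rescaled to 8 bits.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the file cannot be decoded as an image.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backends' errors
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"empty image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 257.0
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.rint(np.clip(arr, 0, 255))
    return arr.astype(np.uint8)


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a grayscale image or boolean mask to an 8-bit PNG/TIFF.

    Masks are written as 0/255. Round-tripping through :func:`read_image`
    is bit-exact for PNG and TIFF.
    """
    a = np.asarray(img)
    if a.dtype == bool:
        a = a.astype(np.uint8) * 255
    else:
        a = as_gray_u8(a)
    parent = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    iio.imwrite(path, a)
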