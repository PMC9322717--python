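"""Reading and writing 8-bit single-channel PNG/TIFF images and masks."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import OutOfRangeError, SchemaError

__all__ = ["read_gray", "write_gray", "read_mask", "write_mask"]


def read_gray(path) -> np.ndarray:
    """Load an 8-bit single-channel image; multi-channel input is rejected
    (no silent RGB-to-gray conversion)."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise SchemaError(
            f"{path}: expected a single-channel image, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise OutOfRangeError(f"{path}: expected 8-bit pixels, got {arr.dtype}")
    return arr


def write_gray(path, img: np.ndarray) -> None:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise SchemaError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise OutOfRangeError("pixel values must fit in 8 bits")
    iio.imwrite(Path(path), arr.astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Load a 0/255 mask PNG as a 0/1 array."""
    arr = read_gray(path)
    return (arr > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a 0/1 mask as a 0/255 single-channel PNG."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    iio.imwrite(Path(path), arr)
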