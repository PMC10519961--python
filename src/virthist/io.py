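"""Image and table I/O: lossless TIFF/PNG round-trips and schema-stable CSV."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_image", "write_image", "read_table", "write_table"]


def write_image(path, array: np.ndarray, bit_depth: int | None = None) -> None:
    """Write a raster as TIFF (any dtype) or PNG (8/16-bit).

    Float arrays in [0, 1] destined for PNG (or TIFF with an explicit
    ``bit_depth``) are scaled to the requested integer range; integer
    arrays are written as-is.
    """
    path = Path(path)
    arr = np.asarray(array)
    if bit_depth is not None:
        if bit_depth == 8:
            arr = np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)
        elif bit_depth == 16:
            arr = np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16)
        else:
            raise ValueError("supported bit depths: 8, 16")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        if arr.dtype not in (np.uint8, np.uint16):
            raise ValueError("PNG requires 8- or 16-bit data (pass bit_depth)")
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format: {suffix}")


def read_image(path) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    if suffix == ".png":
        return iio.imread(path)
    raise ValueError(f"unsupported image format: {suffix}")


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
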