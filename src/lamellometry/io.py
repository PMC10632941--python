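"""Reading and writing raster images.

Inputs must come from lossless formats (TIFF per the acquisition protocol, or
PNG): the fiducial markers are matched by exact RGB value and do not survive
lossy encoders.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

LOSSLESS_SUFFIXES = {".tif", ".tiff", ".png"}


def read_rgb(path: str | os.PathLike) -> np.ndarray:
    """Read an image as an (H, W, 3) uint8 RGB array.

    Grayscale images are broadcast across channels; alpha channels are dropped.
    """
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        # 16-bit TIFFs scale down; bool scales up
        if arr.dtype == bool:
            arr = arr.astype(np.uint8) * 255
        elif np.issubdtype(arr.dtype, np.integer):
            arr = (arr.astype(np.float64) * 255 / np.iinfo(arr.dtype).max).round()
            arr = arr.astype(np.uint8)
        else:
            arr = np.clip(np.round(arr * 255), 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[-1] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr)


def write_image(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write an RGB, grayscale, or boolean raster to ``path``."""
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(path, np.ascontiguousarray(arr))
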