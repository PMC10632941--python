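"""Grayscale conversion, contrast stretch, and column-local binarization.

Under polarized light, lamellae alternate bright and dark along the image
columns once the image is reoriented.  Each pixel is classed bright or dark
relative to the mean intensity of its 20 nearest same-column neighbors — a
column-local adaptive threshold that tolerates slow illumination gradients
across the field.  Short wrong-color runs inside a lamella ("floating
pixels", typically canaliculi or staining noise) are then repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ImageTooShortError
from .preprocess import CroppedImage

#: ITU-R BT.601 luma weights, the standard RGB→gray transform.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass(frozen=True)
class ThresholdParams:
    """Tunables of the binarization stage.

    window_size
        Number of nearest same-column neighbors averaged per pixel
        (default 20, split 10 above / 10 below, shifted inward at the
        image edges so the count stays exact).
    saturation_fraction
        Tail mass clipped at each end in the contrast stretch (default 0.01:
        1% of the data saturates at low and at high intensities).
    max_floating_run
        Largest wrong-color run repaired inside a lamella (default 2).
    """

    window_size: int = 20
    saturation_fraction: float = 0.01
    max_floating_run: int = 2

    def __post_init__(self) -> None:
        if self.window_size < 2 or self.window_size % 2 != 0:
            raise ValueError("window_size must be an even integer >= 2")
        if not (0 <= self.saturation_fraction < 0.5):
            raise ValueError("saturation_fraction must be in [0, 0.5)")
        if self.max_floating_run < 0:
            raise ValueError("max_floating_run must be >= 0")


@dataclass(frozen=True)
class GrayImage:
    """2-D 8-bit intensity raster."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.dtype != np.uint8:
            raise ValueError("pixels must be a 2-D uint8 array")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class BinaryLamellarImage:
    """Boolean raster: True = bright lamella (white), False = dark (black)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.dtype != bool:
            raise ValueError("pixels must be a 2-D boolean array")
        object.__setattr__(self, "pixels", px)


def to_grayscale(image: CroppedImage | np.ndarray) -> GrayImage:
    """Weighted-luma grayscale: round(0.2989 R + 0.5870 G + 0.1140 B)."""
    rgb = image.pixels if isinstance(image, CroppedImage) else np.asarray(image)
    w = np.asarray(LUMA_WEIGHTS)
    gray = rgb.astype(np.float64) @ w
    return GrayImage(pixels=np.clip(np.round(gray), 0, 255).astype(np.uint8))


def stretch_contrast(gray: GrayImage, params: ThresholdParams | None = None) -> GrayImage:
    """Percentile contrast stretch saturating ``saturation_fraction`` per tail.

    Intensities at or below the low quantile map to 0, at or above the high
    quantile to 255, linearly in between (linear-interpolation quantiles).
    A constant image is returned unchanged.
    """
    params = params or ThresholdParams()
    x = gray.pixels.astype(np.float64)
    lo = float(np.quantile(x, params.saturation_fraction))
    hi = float(np.quantile(x, 1.0 - params.saturation_fraction))
    if hi <= lo:
        return GrayImage(pixels=gray.pixels.copy())
    out = np.round(255.0 * (x - lo) / (hi - lo))
    return GrayImage(pixels=np.clip(out, 0, 255).astype(np.uint8))


def binarize_columns(gray: GrayImage, params: ThresholdParams | None = None) -> BinaryLamellarImage:
    """Threshold each pixel against the mean of its nearest in-column neighbors.

    The neighborhood is the ``window_size`` row indices in the pixel's column
    nearest to it, excluding the pixel itself; at the top and bottom edges the
    window shifts inward so exactly ``window_size`` pixels are always used.
    A pixel is bright iff its intensity is *strictly* greater than the
    neighborhood mean (equality maps to dark).
    """
    params = params or ThresholdParams()
    x = gray.pixels.astype(np.float64)
    h, w = x.shape
    win = params.window_size
    if h <= win:
        raise ImageTooShortError(
            f"image height {h} must exceed window_size {win}"
        )
    half = win // 2
    starts = np.clip(np.arange(h) - half, 0, h - 1 - win)
    cs = np.vstack([np.zeros((1, w)), np.cumsum(x, axis=0)])
    window_sums = cs[starts + win + 1] - cs[starts] - x
    bright = x * win > window_sums
    return BinaryLamellarImage(pixels=bright)


def _flip_short_runs(column: np.ndarray, max_run: int) -> np.ndarray:
    """Single top-to-bottom repair pass over one boolean column."""
    # run-length encode
    change = np.nonzero(np.diff(column))[0] + 1
    bounds = np.concatenate([[0], change, [len(column)]])
    runs = [
        [bool(column[bounds[i]]), int(bounds[i + 1] - bounds[i])]
        for i in range(len(bounds) - 1)
    ]
    i = 1
    while i < len(runs) - 1:
        if runs[i][1] <= max_run:
            # flip: merge with both (opposite-colored) neighbors
            runs[i - 1][1] += runs[i][1] + runs[i + 1][1]
            del runs[i : i + 2]
        else:
            i += 1
    return np.concatenate([np.full(n, color, dtype=bool) for color, n in runs])


def fix_floating_pixels(
    binary: BinaryLamellarImage, params: ThresholdParams | None = None
) -> BinaryLamellarImage:
    """Recolor short wrong-color runs to match the surrounding lamella.

    Each column is scanned once, top to bottom: a maximal run of length
    ``<= max_floating_run`` whose neighbors above and below are both the
    opposite color is flipped, and the scan continues on the updated column
    so flips can merge runs.  Runs touching the top or bottom edge are never
    flipped — they are not *within* a lamella.
    """
    params = params or ThresholdParams()
    if params.max_floating_run == 0:
        return BinaryLamellarImage(pixels=binary.pixels.copy())
    out = np.empty_like(binary.pixels)
    for j in range(binary.pixels.shape[1]):
        out[:, j] = _flip_short_runs(binary.pixels[:, j], params.max_floating_run)
    return BinaryLamellarImage(pixels=out)
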