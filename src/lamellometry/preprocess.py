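"""Fiducial-marker detection, reorientation, and ROI cropping.

An operator annotates each micrograph with a yellow rectangle enclosing the
measurement area, red pixels on the rectangle's two top corners and green
pixels on its two bottom corners.  This module locates those markers, rotates
the image so the red pair is horizontal (lamellae then run left-to-right),
and crops to the rectangle's interior.

Coordinates are 0-based ``(row, col)`` with row 0 at the image top; ranges are
half-open.  Rotation angles are in degrees, counterclockwise-positive in the
displayed image, and restricted to ``(-180, 180]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special
from skimage.measure import label

from .errors import (
    AmbiguousMarkerError,
    DegenerateMarkerError,
    MalformedROIError,
    MissingMarkerError,
    MissingROIError,
)
from .io import read_rgb

Point = tuple[int, int]


@dataclass(frozen=True)
class MarkerColors:
    """Exact RGB codes of the annotation markers.

    The defaults are the pixel values the annotation protocol dictates
    (MS Paint's default red and green, and pure yellow).  ``tolerance``
    admits a per-channel deviation of ±k for images that passed through a
    lossy encoder; it defaults to 0 because the protocol assumes lossless
    TIFF round-trips.
    """

    red: tuple[int, int, int] = (237, 28, 36)
    green: tuple[int, int, int] = (34, 177, 76)
    yellow: tuple[int, int, int] = (255, 255, 0)
    tolerance: int = 0

    def __post_init__(self) -> None:
        if len({self.red, self.green, self.yellow}) != 3:
            raise ValueError("marker colors must be pairwise distinct")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class AnnotatedImage:
    """An operator-marked RGB micrograph, the pipeline's real-world input."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an (H, W, 3) uint8 array")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be at least 2x2")
        object.__setattr__(self, "pixels", px)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "AnnotatedImage":
        return cls(pixels=read_rgb(path), source_path=str(path))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class MarkerSet:
    """Detected marker centroids: two red (top) and two green (bottom) points.

    Red points are ordered so the first is closest to the image top (smallest
    row index; ties broken by smaller column).
    """

    red_points: tuple[Point, Point]
    green_points: tuple[Point, Point]

    def __post_init__(self) -> None:
        if len(self.red_points) != 2 or len(self.green_points) != 2:
            raise ValueError("exactly 2 red and 2 green points required")
        if self.red_points[0] == self.red_points[1]:
            raise DegenerateMarkerError("the two red markers coincide")
        if sorted(self.red_points) != list(self.red_points):
            raise ValueError("red points must be ordered top-first")


@dataclass(frozen=True)
class CroppedImage:
    """The sub-image strictly interior to the yellow rectangle."""

    pixels: np.ndarray
    origin_note: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an (H, W, 3) uint8 array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("cropped interior is empty")
        object.__setattr__(self, "pixels", px)


def color_mask(pixels: np.ndarray, rgb: tuple[int, int, int], tolerance: int = 0) -> np.ndarray:
    """Boolean mask of pixels matching ``rgb`` within ±tolerance per channel."""
    target = np.asarray(rgb, dtype=np.int16)
    if tolerance == 0:
        return np.all(pixels == target, axis=-1)
    diff = np.abs(pixels.astype(np.int16) - target)
    return np.all(diff <= tolerance, axis=-1)


def _marker_centroids(mask: np.ndarray, color_name: str, rgb) -> list[Point]:
    labels, n = label(mask, connectivity=2, return_num=True)
    if n < 2:
        raise MissingMarkerError(
            f"expected 2 {color_name} marker components (RGB {tuple(rgb)}), found {n}"
        )
    if n > 2:
        raise AmbiguousMarkerError(
            f"expected 2 {color_name} marker components (RGB {tuple(rgb)}), found {n}"
        )
    points = []
    for lab in (1, 2):
        coords = np.argwhere(labels == lab)
        centroid = coords.mean(axis=0)
        points.append((int(round(centroid[0])), int(round(centroid[1]))))
    return sorted(points)


def detect_markers(image: AnnotatedImage, colors: MarkerColors | None = None) -> MarkerSet:
    """Locate the red and green corner fiducials.

    Marker pixels matching the exact color codes are grouped by
    8-connectivity; each group's centroid (rounded to the nearest pixel) is
    one marker point.  Exactly two components of each color must exist.
    """
    colors = colors or MarkerColors()
    red = _marker_centroids(
        color_mask(image.pixels, colors.red, colors.tolerance), "red", colors.red
    )
    green = _marker_centroids(
        color_mask(image.pixels, colors.green, colors.tolerance), "green", colors.green
    )
    return MarkerSet(red_points=(red[0], red[1]), green_points=(green[0], green[1]))


def _normalize_angle(degrees: float) -> float:
    """Map an angle into (-180, 180]."""
    a = (degrees + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def _rotated_row(point, degrees: float) -> float:
    """Row coordinate of ``point`` after rotating the plane by ``degrees``.

    Centering offsets are irrelevant for row comparisons and omitted.
    """
    c, s = special.cosdg(degrees), special.sindg(degrees)
    return c * point[0] - s * point[1]


def compute_rotation_angle(markers: MarkerSet) -> float:
    """Corrective rotation (degrees) that aligns the red pair horizontally.

    Of the two angles that make the red markers share a row, the one that
    leaves red above green (red marks the rectangle's *top* corners) is
    returned; if green placement cannot disambiguate, the smaller-magnitude
    angle is kept.  Returns 0 when the red markers already share a row.
    """
    (r1, c1), (r2, c2) = markers.red_points
    if (r1, c1) == (r2, c2):
        raise DegenerateMarkerError("red markers coincide; angle undefined")
    base = _normalize_angle(np.degrees(np.arctan2(r2 - r1, c2 - c1)))
    candidates = sorted({base, _normalize_angle(base - 180.0)}, key=abs)
    for angle in candidates:
        red_rows = [_rotated_row(p, angle) for p in markers.red_points]
        green_rows = [_rotated_row(p, angle) for p in markers.green_points]
        if np.mean(red_rows) < np.mean(green_rows):
            return float(angle)
    return float(candidates[0])


def rotate_points(points: np.ndarray, in_shape: tuple[int, int], degrees: float) -> np.ndarray:
    """Forward-map ``(row, col)`` points under :func:`rotate_image`.

    Reproduces the canvas-enlarging geometry of ``scipy.ndimage.rotate`` with
    ``reshape=True``: rotation about the input center, then translation so
    the whole input frame fits in the output canvas.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    h, w = in_shape
    c, s = special.cosdg(degrees), special.sindg(degrees)
    bounds = np.array([[c, s], [-s, c]]) @ np.array(
        [[0, 0, h, h], [0, w, 0, w]], dtype=np.float64
    )
    out_shape = (np.ptp(bounds, axis=1) + 0.5).astype(int)
    in_center = (np.array([h, w]) - 1) / 2.0
    out_center = (out_shape - 1) / 2.0
    fwd = np.array([[c, -s], [s, c]])
    out = (pts - in_center) @ fwd.T + out_center
    return out if np.asarray(points).ndim == 2 else out[0]


def rotate_image(image: AnnotatedImage, degrees: float) -> AnnotatedImage:
    """Rotate by ``degrees`` (counterclockwise-positive) on an enlarged canvas.

    Resampling is nearest-neighbor so the exact marker colors survive; pixels
    falling outside the original frame are black.
    """
    if degrees % 360.0 == 0.0:
        return AnnotatedImage(pixels=image.pixels.copy(), source_path=image.source_path)
    rotated = ndimage.rotate(
        image.pixels, degrees, axes=(1, 0), reshape=True, order=0,
        mode="constant", cval=0,
    )
    return AnnotatedImage(pixels=rotated.astype(np.uint8), source_path=image.source_path)


def _line_indices(mask: np.ndarray, axis: int) -> np.ndarray:
    """Indices along ``axis`` that qualify as yellow lines.

    A row (or column) counts as a line when at least half of its span across
    the yellow bounding box matches yellow — nearest-neighbor rotation
    perforates thin lines, so exact fullness cannot be required.
    """
    ys, xs = np.nonzero(mask)
    if axis == 0:
        span = mask[:, xs.min() : xs.max() + 1]
    else:
        span = mask[ys.min() : ys.max() + 1, :].T
    frac = span.mean(axis=1)
    return np.nonzero(frac >= 0.5)[0]


def crop_to_roi(image: AnnotatedImage, colors: MarkerColors | None = None) -> CroppedImage:
    """Crop to the area strictly inside the yellow rectangle.

    Run on the *rotated* image, where the rectangle is axis-aligned.  The
    interior spans the open interval between the innermost yellow rows above
    and below the rectangle center (likewise for columns); any residual
    marker-colored pixels on the interior border are trimmed off.
    """
    colors = colors or MarkerColors()
    yellow = color_mask(image.pixels, colors.yellow, colors.tolerance)
    if not yellow.any():
        raise MissingROIError(
            f"no pixels of the yellow ROI color {colors.yellow} found"
        )
    ys, xs = np.nonzero(yellow)
    center_r = (ys.min() + ys.max()) / 2.0
    center_c = (xs.min() + xs.max()) / 2.0

    rows = _line_indices(yellow, axis=0)
    cols = _line_indices(yellow, axis=1)
    top = rows[rows < center_r]
    bottom = rows[rows > center_r]
    left = cols[cols < center_c]
    right = cols[cols > center_c]
    if len(top) == 0 or len(bottom) == 0 or len(left) == 0 or len(right) == 0:
        raise MalformedROIError("yellow pixels do not form a closed rectangle")

    r0, r1 = int(top.max()) + 1, int(bottom.min())
    c0, c1 = int(left.max()) + 1, int(right.min())
    if r0 >= r1 or c0 >= c1:
        raise MalformedROIError("yellow rectangle has an empty interior")

    sub = image.pixels[r0:r1, c0:c1].copy()
    marker = (
        color_mask(sub, colors.yellow, colors.tolerance)
        | color_mask(sub, colors.red, colors.tolerance)
        | color_mask(sub, colors.green, colors.tolerance)
    )
    # Nearest-neighbor de-rotation can scatter a few annotation-line pixels
    # just inside the interior, occluding the tissue sample there.  Repair
    # each from the nearest non-marker pixel in its column (the tissue
    # continues across the residue), mirroring the floating-pixel repair
    # philosophy; discarding whole rows would bias the edge lamellae thin.
    if marker.any():
        for r, c in np.argwhere(marker):
            col_ok = np.nonzero(~marker[:, c])[0]
            if col_ok.size == 0:
                raise MalformedROIError(
                    f"interior column {c0 + c} consists entirely of marker colors"
                )
            nearest = col_ok[np.argmin(np.abs(col_ok - r))]
            sub[r, c] = sub[nearest, c]

    return CroppedImage(
        pixels=sub,
        origin_note=f"rows {r0}:{r1}, cols {c0}:{c1} of rotated image",
    )
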