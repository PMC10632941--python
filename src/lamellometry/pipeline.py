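"""End-to-end orchestration: annotated image in, thickness table out.

Runs preprocess → binarize → measure, optionally writing the six diagnostic
stage images (annotated input, rotated, cropped, contrast-stretched
grayscale, binary, and the final image with rejected columns grayed out)
plus machine-readable results.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import binarize as _bin
from . import measure as _measure
from . import preprocess as _pre
from .binarize import BinaryLamellarImage, ThresholdParams
from .io import write_image
from .measure import DEFAULT_PIXEL_LENGTH_UM, ExpectedCounts, LamellarMeasurement
from .preprocess import AnnotatedImage, MarkerColors

log = logging.getLogger("lamellometry")

COUNTING_REMINDER = (
    "Counting rules: start from the band matching the color of the top row of "
    "pixels; count bright and dark bands downward; stop at a band mostly cut "
    "off by the bottom of the frame."
)


@dataclass(frozen=True)
class RunConfig:
    """All inputs of one measurement run.

    ``filepath`` is the pre-processed (annotated) sample image;
    ``n_bright``/``n_dark`` are the operator's lamella counts;
    ``pixel_length_um`` is the physical pixel pitch (0.3185 µm at 20x).
    """

    filepath: str
    n_bright: int = 1
    n_dark: int = 1
    pixel_length_um: float = DEFAULT_PIXEL_LENGTH_UM
    colors: MarkerColors = field(default_factory=MarkerColors)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    drop_partial_bottom: bool = True
    output_dir: str | None = None

    @property
    def expected(self) -> ExpectedCounts:
        return ExpectedCounts(n_bright=self.n_bright, n_dark=self.n_dark)


def _preprocess(config: RunConfig):
    image = AnnotatedImage.load(config.filepath)
    markers = _pre.detect_markers(image, config.colors)
    angle = _pre.compute_rotation_angle(markers)
    log.info("detected rotation angle: %.4f deg", angle)
    rotated = _pre.rotate_image(image, angle)
    cropped = _pre.crop_to_roi(rotated, config.colors)
    log.info("crop bounds: %s", cropped.origin_note)
    return image, rotated, cropped


def _binarize(cropped, config: RunConfig) -> tuple:
    gray = _bin.to_grayscale(cropped)
    stretched = _bin.stretch_contrast(gray, config.threshold)
    binary = _bin.binarize_columns(stretched, config.threshold)
    fixed = _bin.fix_floating_pixels(binary, config.threshold)
    return stretched, fixed


def grayed_column_image(binary: BinaryLamellarImage, mask: np.ndarray) -> np.ndarray:
    """RGB rendering of the binary image with rejected columns mid-gray."""
    out = np.where(binary.pixels[..., None], 255, 0).astype(np.uint8)
    out = np.repeat(out, 3, axis=-1) if out.shape[-1] == 1 else out
    out[:, ~np.asarray(mask, dtype=bool), :] = 128
    return out


def run_pipeline(config: RunConfig) -> LamellarMeasurement:
    """Execute the full measurement on one annotated image.

    When ``config.output_dir`` is set, writes ``stage_1.png`` … ``stage_6.png``
    and ``results.csv`` / ``results.json`` there.
    """
    image, rotated, cropped = _preprocess(config)
    stretched, fixed = _binarize(cropped, config)

    runs = _measure.run_length_encode(fixed)
    first = _measure.majority_first_color(runs)
    mask, n_first, n_count = _measure.column_rejection_reasons(
        runs, config.expected, first, config.drop_partial_bottom
    )
    log.info(
        "columns: %d total, %d retained (%d rejected by first-color, %d by count)",
        runs.n_columns, int(mask.sum()), n_first, n_count,
    )
    if not mask.any():
        raise _measure.AllColumnsRejectedError(
            f"all {runs.n_columns} columns rejected "
            f"({n_first} by first-pixel color, {n_count} by lamella count); "
            "re-count the lamellae on the binary preview (see count_assist) "
            "or re-draw the measurement rectangle"
        )
    result = _measure.average_thicknesses(
        runs, mask, config.expected, config.pixel_length_um, config.drop_partial_bottom
    )

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_image(out / "stage_1_annotated.png", image.pixels)
        write_image(out / "stage_2_rotated.png", rotated.pixels)
        write_image(out / "stage_3_cropped.png", cropped.pixels)
        write_image(out / "stage_4_grayscale.png", stretched.pixels)
        write_image(out / "stage_5_binary.png", fixed.pixels)
        write_image(out / "stage_6_retained.png", grayed_column_image(fixed, mask))
        result.write_csv(out / "results.csv")
        result.write_json(out / "results.json")
    return result


def count_assist(config: RunConfig) -> BinaryLamellarImage:
    """Preprocess + binarize only: the preview used to count lamellae.

    Writes ``count_preview.png`` when ``output_dir`` is set.  The operator
    counts bands on this preview to choose ``n_bright``/``n_dark``.
    """
    _, _, cropped = _preprocess(config)
    _, fixed = _binarize(cropped, config)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_image(out / "count_preview.png", fixed.pixels)
    return fixed
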