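import numpy as np
import pytest

import lamellometry as lm


def analyze(spec, threshold=None, drop_partial_bottom=True):
    """Run the full in-memory pipeline on a generated fixture.

    Returns (measurement, ground_truth).
    """
    threshold = threshold or lm.ThresholdParams()
    img, truth = lm.generate_fixture(spec)
    markers = lm.detect_markers(img)
    angle = lm.compute_rotation_angle(markers)
    cropped = lm.crop_to_roi(lm.rotate_image(img, angle))
    gray = lm.stretch_contrast(lm.to_grayscale(cropped), threshold)
    binary = lm.fix_floating_pixels(lm.binarize_columns(gray, threshold), threshold)
    runs = lm.run_length_encode(binary)
    first = lm.majority_first_color(runs)
    mask = lm.filter_columns(runs, truth.expected, first, drop_partial_bottom)
    result = lm.average_thicknesses(
        runs, mask, truth.expected, drop_partial_bottom=drop_partial_bottom
    )
    return result, truth


def thickness_errors_px(result, truth):
    """Max |recovered - true| per color class, in pixels.

    Computed in micrometers and rescaled, so an exactly-recovered lamella
    (every retained run equal to truth) yields an error of exactly 0.0.
    """
    px = result.pixel_length_um
    true_b = [t for c, t in zip(truth.band_colors, truth.band_thicknesses_px) if c == "bright"]
    true_d = [t for c, t in zip(truth.band_colors, truth.band_thicknesses_px) if c == "dark"]
    err_b = np.abs(np.array(result.avg_bright_um) - np.array(true_b) * px)
    err_d = np.abs(np.array(result.avg_dark_um) - np.array(true_d) * px)
    return float(max(err_b.max(), err_d.max())) / px


@pytest.fixture
def clean_spec():
    return lm.FixtureSpec()


def make_columns(*cols):
    """Build a ColumnRuns from lists of (bright, length) tuples."""
    columns = [[lm.Run(bool(b), int(n)) for b, n in col] for col in cols]
    heights = {sum(r.length for r in col) for col in columns}
    assert len(heights) == 1, "columns must share a height"
    return lm.ColumnRuns(columns=columns, height=heights.pop())
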