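"""Synthetic annotated lamellar micrographs with ground truth.

The clinical micrographs this method was developed on are confidential, so
this module renders stand-ins: alternating bright/dark horizontal bands
(lamellae seen under polarized light), optional Gaussian intensity noise and
circular blob defects emulating osteocyte lacunae, a global rotation, and
the full operator annotation — yellow ROI rectangle aligned to the band
direction, red pixels on its top corners, green on its bottom corners — so
the pipeline must detect the markers and undo the rotation exactly as it
would on real data.

Every generated image carries a :class:`FixtureGroundTruth` recording true
band thicknesses, marker coordinates and expected counts, which the test
suite uses as its oracle.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import disk, line

from .errors import DefectOutsideROIError, FixtureSpecError
from .measure import ExpectedCounts
from .preprocess import AnnotatedImage, MarkerColors, rotate_points
from .io import write_image

Blob = tuple[tuple[int, int], int, int]  # ((row, col), radius, intensity)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic annotated micrograph.

    band_thicknesses
        Ordered top-to-bottom list of ``(color, thickness_px)`` with color
        ``"bright"`` or ``"dark"``; colors must alternate.  The ROI interior
        is exactly the band stack, so these are the ground-truth thicknesses.
    bright_intensity / dark_intensity
        8-bit band levels.  When noise is added they must differ by at least
        40 levels so the bands stay separable.
    rotation_deg
        Global scene rotation; the annotation rectangle follows the bands,
        so the pipeline has to undo this rotation.
    noise_sd
        Standard deviation of additive Gaussian intensity noise.
    defects
        Blobs ``((row, col), radius, intensity)`` in band (ROI-interior)
        coordinates, emulating osteocyte lacunae.
    roi_margin
        Pixels of band-colored padding between the yellow rectangle and the
        canvas edge (the tissue continues beyond the measurement area).
    sinusoidal
        Replace hard band edges with a smooth sinusoidal intensity profile,
        closer to real polarized-light gradation; off by default so tests
        have exact band-boundary oracles.
    """

    band_thicknesses: tuple[tuple[str, int], ...] = (
        ("bright", 10), ("dark", 8), ("bright", 12), ("dark", 9), ("bright", 11),
    )
    width: int = 120
    bright_intensity: int = 200
    dark_intensity: int = 55
    rotation_deg: float = 0.0
    noise_sd: float = 0.0
    defects: tuple[Blob, ...] = ()
    roi_margin: int = 12
    sinusoidal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        bands = tuple((str(c), int(t)) for c, t in self.band_thicknesses)
        object.__setattr__(self, "band_thicknesses", bands)
        object.__setattr__(self, "defects", tuple(self.defects))
        if len(bands) < 2:
            raise FixtureSpecError("need at least one bright and one dark band")
        for color, t in bands:
            if color not in ("bright", "dark"):
                raise FixtureSpecError(f"unknown band color {color!r}")
            if t < 1:
                raise FixtureSpecError("band thicknesses must be >= 1 px")
        for (c1, _), (c2, _) in zip(bands, bands[1:]):
            if c1 == c2:
                raise FixtureSpecError("band colors must alternate")
        if self.width < 1 or self.roi_margin < 2:
            raise FixtureSpecError("width must be >= 1 and roi_margin >= 2")
        if self.noise_sd > 0 and abs(self.bright_intensity - self.dark_intensity) < 40:
            raise FixtureSpecError(
                "bright/dark intensities must differ by >= 40 when noise_sd > 0"
            )

    @property
    def roi_height(self) -> int:
        return sum(t for _, t in self.band_thicknesses)

    @property
    def expected(self) -> ExpectedCounts:
        nb = sum(1 for c, _ in self.band_thicknesses if c == "bright")
        nd = len(self.band_thicknesses) - nb
        return ExpectedCounts(n_bright=nb, n_dark=nd)


@dataclass(frozen=True)
class FixtureGroundTruth:
    """Everything true-by-construction about a generated fixture."""

    band_mask: np.ndarray          # ROI-interior raster, True = bright
    band_colors: list[str]
    band_thicknesses_px: list[int]
    red_points: list[tuple[int, int]]    # in final-image coordinates, top-first
    green_points: list[tuple[int, int]]
    roi_shape: tuple[int, int]     # (height, width) of the ROI interior
    expected: ExpectedCounts
    rotation_deg: float
    seed: int
    defects: tuple[Blob, ...] = ()

    def defect_columns(self) -> set[int]:
        """ROI-interior column indices intersected by any defect blob."""
        cols: set[int] = set()
        for (r, c), radius, _ in self.defects:
            lo = max(0, c - radius)
            hi = min(self.roi_shape[1] - 1, c + radius)
            cols.update(range(lo, hi + 1))
        return cols

    def to_dict(self) -> dict:
        return {
            "band_mask": np.asarray(self.band_mask, dtype=int).tolist(),
            "band_colors": list(self.band_colors),
            "band_thicknesses_px": [int(t) for t in self.band_thicknesses_px],
            "red_points": [list(p) for p in self.red_points],
            "green_points": [list(p) for p in self.green_points],
            "roi_shape": list(self.roi_shape),
            "expected": {"n_bright": self.expected.n_bright, "n_dark": self.expected.n_dark},
            "rotation_deg": float(self.rotation_deg),
            "seed": int(self.seed),
            "defects": [[list(center), int(r), int(i)] for center, r, i in self.defects],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureGroundTruth":
        return cls(
            band_mask=np.asarray(d["band_mask"], dtype=bool),
            band_colors=list(d["band_colors"]),
            band_thicknesses_px=list(d["band_thicknesses_px"]),
            red_points=[tuple(p) for p in d["red_points"]],
            green_points=[tuple(p) for p in d["green_points"]],
            roi_shape=tuple(d["roi_shape"]),
            expected=ExpectedCounts(**d["expected"]),
            rotation_deg=float(d["rotation_deg"]),
            seed=int(d["seed"]),
            defects=tuple((tuple(c), r, i) for c, r, i in d["defects"]),
        )


def _band_profile(spec: FixtureSpec) -> np.ndarray:
    """Per-row intensity of the band stack (float, length roi_height)."""
    profile = np.empty(spec.roi_height, dtype=np.float64)
    mid = (spec.bright_intensity + spec.dark_intensity) / 2.0
    amp = (spec.bright_intensity - spec.dark_intensity) / 2.0
    row = 0
    for color, t in spec.band_thicknesses:
        if spec.sinusoidal:
            tt = (np.arange(t) + 0.5) / t
            wave = amp * np.sin(np.pi * tt)
            profile[row : row + t] = mid + wave if color == "bright" else mid - wave
        else:
            level = spec.bright_intensity if color == "bright" else spec.dark_intensity
            profile[row : row + t] = level
        row += t
    return profile


def inject_defect(
    pixels: np.ndarray,
    blob: Blob,
    roi_bounds: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Set all pixels within ``radius`` of the blob center to ``intensity``.

    ``roi_bounds`` is a half-open ``(r0, r1, c0, c1)`` box the whole disk
    must lie inside (defaults to the full image).  Returns a modified copy.
    """
    (r, c), radius, intensity = blob
    out = np.array(pixels, copy=True)
    h, w = out.shape[:2]
    r0, r1, c0, c1 = roi_bounds if roi_bounds is not None else (0, h, 0, w)
    if radius < 0:
        raise DefectOutsideROIError("defect radius must be >= 0")
    if not (r0 + radius <= r < r1 - radius and c0 + radius <= c < c1 - radius):
        raise DefectOutsideROIError(
            f"defect at {(r, c)} radius {radius} does not fit inside rows "
            f"[{r0},{r1}) cols [{c0},{c1})"
        )
    rr, cc = disk((r, c), radius + 0.5, shape=(h, w))
    out[rr, cc] = intensity
    return out


def generate_fixture(
    spec: FixtureSpec, colors: MarkerColors | None = None
) -> tuple[AnnotatedImage, FixtureGroundTruth]:
    """Render an annotated synthetic micrograph and its ground truth.

    Bands are drawn horizontally, extended beyond the rectangle on all sides
    (tissue continues outside the measurement area), noise and defects are
    applied, the whole scene is rotated by ``rotation_deg`` with bilinear
    resampling (data generation, not the method under test), and the yellow
    rectangle plus exact-color corner markers are stamped *after* rotation so
    annotation colors are exact.  Deterministic given ``spec.seed``.
    """
    colors = colors or MarkerColors()
    m = spec.roi_margin
    h, w = spec.roi_height, spec.width
    ch, cw = h + 2 * m, w + 2 * m

    profile = _band_profile(spec)
    column = np.concatenate(
        [np.full(m, profile[0]), profile, np.full(m, profile[-1])]
    )
    canvas = np.tile(column[:, None], (1, cw))

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)

    for blob in spec.defects:
        (r, c), radius, intensity = blob
        canvas = inject_defect(
            canvas, ((r + m, c + m), radius, intensity), roi_bounds=(m, m + h, m, m + w)
        )

    gray = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)

    # rectangle sides are 2 px thick (annotation tools draw multi-pixel
    # lines), thickened outward so the interior is exactly the band stack;
    # the inner ring carries the corner markers
    rings = [
        np.array(
            [[m - k, m - k], [m - k, m + w + k - 1],
             [m + h + k - 1, m - k], [m + h + k - 1, m + w + k - 1]],
            dtype=np.float64,
        )
        for k in (1, 2)
    ]  # each: TL, TR, BL, BR
    if spec.rotation_deg % 360.0 != 0.0:
        rgb = ndimage.rotate(
            rgb, spec.rotation_deg, axes=(1, 0), reshape=True, order=1,
            mode="constant", cval=0,
        ).astype(np.uint8)
        rings = [rotate_points(ring, (ch, cw), spec.rotation_deg) for ring in rings]

    def _round(ring):
        return [
            (int(np.clip(round(r), 0, rgb.shape[0] - 1)),
             int(np.clip(round(c), 0, rgb.shape[1] - 1)))
            for r, c in ring
        ]

    inner, outer = _round(rings[0]), _round(rings[1])
    for tl_, tr_, bl_, br_ in (outer, inner):
        for a, b in ((tl_, tr_), (tr_, br_), (br_, bl_), (bl_, tl_)):
            rr, cc = line(*a, *b)
            rgb[rr, cc] = colors.yellow
    tl, tr, bl, br = inner
    rgb[tl[0], tl[1]] = colors.red
    rgb[tr[0], tr[1]] = colors.red
    rgb[bl[0], bl[1]] = colors.green
    rgb[br[0], br[1]] = colors.green

    starts = np.cumsum([0] + [t for _, t in spec.band_thicknesses[:-1]])
    band_mask = np.zeros((h, w), dtype=bool)
    for (color, t), start in zip(spec.band_thicknesses, starts):
        if color == "bright":
            band_mask[start : start + t, :] = True

    truth = FixtureGroundTruth(
        band_mask=band_mask,
        band_colors=[c for c, _ in spec.band_thicknesses],
        band_thicknesses_px=[t for _, t in spec.band_thicknesses],
        red_points=sorted([tl, tr]),
        green_points=sorted([bl, br]),
        roi_shape=(h, w),
        expected=spec.expected,
        rotation_deg=spec.rotation_deg,
        seed=spec.seed,
        defects=spec.defects,
    )
    return AnnotatedImage(pixels=rgb, source_path="<synthetic>"), truth


def write_fixture(
    spec: FixtureSpec, out_prefix: str | os.PathLike, colors: MarkerColors | None = None
) -> tuple[str, str]:
    """Write ``<prefix>.tif`` and a ``<prefix>.json`` ground-truth sidecar."""
    image, truth = generate_fixture(spec, colors)
    tif = f"{out_prefix}.tif"
    js = f"{out_prefix}.json"
    write_image(tif, image.pixels)
    with open(js, "w") as fh:
        json.dump(truth.to_dict(), fh)
    return tif, js


def standard_suite() -> dict[str, FixtureSpec]:
    """A small battery of named specs covering the conditions tests exercise."""
    return {
        "clean": FixtureSpec(),
        "thin_bands": FixtureSpec(
            band_thicknesses=tuple(
                ("bright" if i % 2 == 0 else "dark", 3) for i in range(21)
            ),
        ),
        # bright bands are capped by the threshold window (see binarize);
        # dark bands may be arbitrarily thick
        "thick_bands": FixtureSpec(
            band_thicknesses=(
                ("bright", 20), ("dark", 30), ("bright", 18),
                ("dark", 25), ("bright", 20),
            ),
        ),
        "rotated": FixtureSpec(rotation_deg=10.0, roi_margin=16),
        "noisy": FixtureSpec(noise_sd=12.0, seed=7),
        # dark-intensity blob centered in the third (bright) band
        "lacuna": FixtureSpec(
            defects=(((24, 60), 4, 55),), seed=3,
        ),
    }
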