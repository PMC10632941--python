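"""Run-length measurement of lamellae and quality-based column rejection.

Each pixel column of the binary measurement image is run-length encoded; a
run of bright (dark) pixels is one crossing of a bright (dark) lamella.
Columns are rejected when (a) they start with the minority first-pixel color
— the first lamella was clipped or an outside lamella leaked in — or (b)
they do not contain exactly the operator-counted numbers of bright and dark
lamellae.  Thickness of lamella *i* is the mean pixel length of the *i*-th
same-color run across retained columns, converted to micrometers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .binarize import BinaryLamellarImage
from .errors import AllColumnsRejectedError

#: physical pixel pitch at 20x magnification, micrometers per pixel
DEFAULT_PIXEL_LENGTH_UM = 0.3185


class Run(NamedTuple):
    """A maximal vertical run of same-class pixels in one column."""

    bright: bool
    length: int


@dataclass(frozen=True)
class ColumnRuns:
    """Per-column run-length encoding of a binary measurement image."""

    columns: list[list[Run]]
    height: int

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class ExpectedCounts:
    """Operator-counted numbers of measurable bright and dark lamellae.

    Bright and dark bands alternate, so the counts may differ by at most one.
    """

    n_bright: int
    n_dark: int

    def __post_init__(self) -> None:
        if self.n_bright < 1 or self.n_dark < 1:
            raise ValueError("expected counts must be >= 1")
        if abs(self.n_bright - self.n_dark) > 1:
            raise ValueError("bright and dark counts may differ by at most 1")

    @property
    def total(self) -> int:
        return self.n_bright + self.n_dark


@dataclass(frozen=True)
class LamellarMeasurement:
    """Final per-lamella average thicknesses and column bookkeeping.

    ``n_sets`` is the total number of pixel columns in the ROI; ``ng_sets``
    the number retained after quality filtering ("good sets").
    """

    avg_bright_um: list[float]
    avg_dark_um: list[float]
    n_sets: int
    ng_sets: int
    retained_mask: np.ndarray
    pixel_length_um: float = DEFAULT_PIXEL_LENGTH_UM

    def __post_init__(self) -> None:
        mask = np.asarray(self.retained_mask, dtype=bool)
        object.__setattr__(self, "retained_mask", mask)
        if int(mask.sum()) != self.ng_sets or self.ng_sets > self.n_sets:
            raise ValueError("retained_mask inconsistent with ng_sets/n_sets")
        if any(t <= 0 for t in self.avg_bright_um + self.avg_dark_um):
            raise ValueError("thicknesses must be positive")

    def to_dict(self) -> dict:
        return {
            "avg_bright_um": [float(v) for v in self.avg_bright_um],
            "avg_dark_um": [float(v) for v in self.avg_dark_um],
            "n_sets": int(self.n_sets),
            "ng_sets": int(self.ng_sets),
            "retained_mask": [bool(v) for v in self.retained_mask],
            "pixel_length_um": float(self.pixel_length_um),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LamellarMeasurement":
        return cls(
            avg_bright_um=list(d["avg_bright_um"]),
            avg_dark_um=list(d["avg_dark_um"]),
            n_sets=int(d["n_sets"]),
            ng_sets=int(d["ng_sets"]),
            retained_mask=np.asarray(d["retained_mask"], dtype=bool),
            pixel_length_um=float(d["pixel_length_um"]),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per lamella: index within its color class, color, mean µm."""
        rows = [
            {"lamella": i + 1, "color": "bright", "avg_thickness_um": round(v, 4)}
            for i, v in enumerate(self.avg_bright_um)
        ] + [
            {"lamella": i + 1, "color": "dark", "avg_thickness_um": round(v, 4)}
            for i, v in enumerate(self.avg_dark_um)
        ]
        return pd.DataFrame(rows, columns=["lamella", "color", "avg_thickness_um"])

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def read_json(cls, path: str | os.PathLike) -> "LamellarMeasurement":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def write_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def run_length_encode(binary: BinaryLamellarImage) -> ColumnRuns:
    """Exact maximal-run decomposition of each column, top to bottom."""
    px = binary.pixels
    columns: list[list[Run]] = []
    for j in range(px.shape[1]):
        col = px[:, j]
        change = np.nonzero(np.diff(col))[0] + 1
        bounds = np.concatenate([[0], change, [len(col)]])
        columns.append(
            [
                Run(bool(col[bounds[i]]), int(bounds[i + 1] - bounds[i]))
                for i in range(len(bounds) - 1)
            ]
        )
    return ColumnRuns(columns=columns, height=px.shape[0])


def majority_first_color(runs: ColumnRuns) -> bool:
    """Color (True = bright) beginning the majority of columns; tie → bright."""
    if runs.n_columns < 1:
        raise ValueError("need at least one column")
    n_bright = sum(1 for col in runs.columns if col[0].bright)
    n_dark = runs.n_columns - n_bright
    return n_bright >= n_dark


def _effective_runs(
    col: list[Run], expected: ExpectedCounts, drop_partial_bottom: bool
) -> list[Run]:
    """Runs used for counting/measurement in one column.

    The operator's counting rule stops at a band mostly cut off by the bottom
    of the frame, yet that band still appears as a final run.  When a column
    has exactly one run too many, the final run — which by construction
    touches the bottom edge — is treated as that partial band and dropped.
    """
    if drop_partial_bottom and len(col) == expected.total + 1:
        return col[:-1]
    return col


def column_rejection_reasons(
    runs: ColumnRuns,
    expected: ExpectedCounts,
    first: bool,
    drop_partial_bottom: bool = True,
) -> tuple[np.ndarray, int, int]:
    """Retained-column mask plus tallies of each rejection criterion.

    Returns ``(mask, n_first_color_fail, n_count_fail)``; a column failing
    both criteria is tallied under the first-color criterion (the order the
    filters are applied in).
    """
    mask = np.zeros(runs.n_columns, dtype=bool)
    n_first = n_count = 0
    for j, col in enumerate(runs.columns):
        if col[0].bright != first:
            n_first += 1
            continue
        eff = _effective_runs(col, expected, drop_partial_bottom)
        nb = sum(1 for r in eff if r.bright)
        nd = len(eff) - nb
        if nb == expected.n_bright and nd == expected.n_dark:
            mask[j] = True
        else:
            n_count += 1
    return mask, n_first, n_count


def filter_columns(
    runs: ColumnRuns,
    expected: ExpectedCounts,
    first: bool,
    drop_partial_bottom: bool = True,
) -> np.ndarray:
    """Boolean mask of columns passing both quality criteria.

    A column is retained iff its first run has the majority color ``first``
    and it contains exactly the expected numbers of bright and dark runs
    (after dropping a bottom-edge partial band, see
    :func:`column_rejection_reasons`).
    """
    mask, _, _ = column_rejection_reasons(runs, expected, first, drop_partial_bottom)
    if not mask.any():
        raise AllColumnsRejectedError(
            "no column matches the expected lamella counts "
            f"({expected.n_bright} bright / {expected.n_dark} dark); "
            "re-count the lamellae on the binary preview or re-draw the ROI"
        )
    return mask


def average_thicknesses(
    runs: ColumnRuns,
    mask: np.ndarray,
    expected: ExpectedCounts,
    pixel_length_um: float = DEFAULT_PIXEL_LENGTH_UM,
    drop_partial_bottom: bool = True,
) -> LamellarMeasurement:
    """Average each lamella's pixel width across retained columns, in µm.

    Lamella identity is positional: the *i*-th bright run in one retained
    column corresponds to the *i*-th bright run in every other (guaranteed by
    the count and first-color filters).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != runs.n_columns:
        raise ValueError("mask length must equal the number of columns")
    retained = [runs.columns[j] for j in np.nonzero(mask)[0]]
    if not retained:
        raise AllColumnsRejectedError("no retained columns to average")
    bright_px = np.zeros((expected.n_bright, len(retained)))
    dark_px = np.zeros((expected.n_dark, len(retained)))
    for k, col in enumerate(retained):
        eff = _effective_runs(col, expected, drop_partial_bottom)
        bright_px[:, k] = [r.length for r in eff if r.bright]
        dark_px[:, k] = [r.length for r in eff if not r.bright]
    return LamellarMeasurement(
        avg_bright_um=list(bright_px.mean(axis=1) * pixel_length_um),
        avg_dark_um=list(dark_px.mean(axis=1) * pixel_length_um),
        n_sets=runs.n_columns,
        ng_sets=len(retained),
        retained_mask=mask,
        pixel_length_um=pixel_length_um,
    )
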