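"""Method-agreement statistics: paired percent differences and the exact
two-sided paired sign test.

Used to compare automated thickness measurements against manual reference
measurements of the same lamellae.  The manual measurement is taken as the
reference (denominator) of the percent difference, since it is the gold
standard being validated against; note the mean |percent difference| is
sensitive to this choice.  Differences between paired thickness measurements
are typically not normally distributed, which motivates the nonparametric
sign test (any standard normality test, e.g. a Lilliefors test, can confirm
this on real data; none is re-implemented here).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .errors import AllZeroDifferencesError


@dataclass(frozen=True)
class PairedMeasurements:
    """Automated and manual thicknesses (µm) of the same lamellae, paired."""

    automated: np.ndarray
    manual: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.automated, dtype=np.float64)
        m = np.asarray(self.manual, dtype=np.float64)
        if a.ndim != 1 or a.shape != m.shape or a.size < 1:
            raise ValueError("automated and manual must be equal-length 1-D, n >= 1")
        if (a <= 0).any() or (m <= 0).any():
            raise ValueError("thicknesses must be positive")
        object.__setattr__(self, "automated", a)
        object.__setattr__(self, "manual", m)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "PairedMeasurements":
        """Read a 2-column CSV (automated, manual); a header row is allowed."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("expected a CSV with two columns: automated, manual")
        return cls(automated=df.iloc[:, 0].to_numpy(), manual=df.iloc[:, 1].to_numpy())


def percent_differences(pairs: PairedMeasurements) -> np.ndarray:
    """Signed percent difference per pair: 100·(automated − manual)/manual."""
    return 100.0 * (pairs.automated - pairs.manual) / pairs.manual


def mean_absolute_percent_difference(pairs: PairedMeasurements) -> float:
    """Mean of |percent difference| across all pairs."""
    return float(np.mean(np.abs(percent_differences(pairs))))


def sign_test_two_sided(differences) -> float:
    """Exact two-sided paired sign test on the median of the differences.

    Zeros are discarded (classical convention).  With n nonzero differences
    and k = min(#positive, #negative), the p-value is the exact binomial
    tail ``min(1, 2·Σ_{j≤k} C(n,j)/2^n)`` — no normal approximation.
    """
    d = np.asarray(differences, dtype=np.float64)
    if d.size < 1:
        raise ValueError("need at least one difference")
    d = d[d != 0]
    if d.size == 0:
        raise AllZeroDifferencesError("all paired differences are zero")
    n = int(d.size)
    k = int(min((d > 0).sum(), (d < 0).sum()))
    tail = sum(comb(n, j) for j in range(k + 1))
    return min(1.0, 2.0 * tail / 2**n)


def agreement_summary(pairs: PairedMeasurements) -> dict:
    """n, mean |%diff|, and sign-test p-value for a paired dataset."""
    return {
        "n": int(pairs.automated.size),
        "mean_abs_percent_diff": mean_absolute_percent_difference(pairs),
        "sign_test_p": sign_test_two_sided(pairs.automated - pairs.manual),
    }


def write_agreement_summary(pairs: PairedMeasurements, path: str | os.PathLike) -> dict:
    summary = agreement_summary(pairs)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
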