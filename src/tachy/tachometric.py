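"""Sliding-bin tachometric curves: fraction correct vs. raw processing time.

A curve is evaluated on a regular grid of bin centers (default step 1 ms).
Each bin collects the trials whose rpt lies within ``bin_width / 2`` of the
center, both edges inclusive; the fraction correct and an exact
(Clopper-Pearson) binomial confidence interval are computed per bin.  Bins
with no trials are undefined (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TachometricCurve:
    """Fraction correct vs rpt on a sliding-bin grid.

    All arrays share the length of ``centers``.  ``frac_correct`` is NaN
    where ``n_total == 0``.
    """

    centers: np.ndarray
    n_total: np.ndarray
    n_correct: np.ndarray
    frac_correct: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    bin_width: float
    ci_level: float = 0.95
    meta: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of bins containing at least one trial."""
        return self.n_total > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "center_ms": self.centers,
                "n_total": self.n_total,
                "n_correct": self.n_correct,
                "frac_correct": self.frac_correct,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def clopper_pearson(k: np.ndarray, n: np.ndarray, level: float = 0.95):
    """Exact binomial CI bounds for k successes out of n, vectorized.

    Returns (low, high); both are NaN where n == 0.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):
        low = sps.beta.ppf(alpha / 2, k, n - k + 1)
        high = sps.beta.ppf(1 - alpha / 2, k + 1, n - k)
    low = np.where(k == 0, 0.0, low)
    high = np.where(k == n, 1.0, high)
    low = np.where(n == 0, np.nan, low)
    high = np.where(n == 0, np.nan, high)
    return low, high


def compute_curve(
    trials: pd.DataFrame,
    bin_width: float = 31.0,
    bin_step: float = 1.0,
    grid: tuple[float, float] = (0.0, 300.0),
    ci_level: float = 0.95,
    meta: dict | None = None,
) -> TachometricCurve:
    """Build the tachometric curve for a (pre-filtered) trial table.

    For each grid center ``c`` the bin is the closed interval
    ``[c - bin_width/2, c + bin_width/2]``; a trial at exactly half-width
    distance counts in.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if bin_step <= 0:
        raise ValueError("bin_step must be > 0")

    centers = np.arange(grid[0], grid[1] + 0.5 * bin_step, bin_step, dtype=float)
    rpt = np.asarray(trials["rpt"], dtype=float)
    correct = np.asarray(trials["correct"], dtype=bool)

    order = np.argsort(rpt, kind="stable")
    rpt_s = rpt[order]
    # cumulative correct counts over rpt-sorted trials; csum[i] = # correct in first i
    csum = np.concatenate([[0], np.cumsum(correct[order])])

    half = bin_width / 2.0
    lo = np.searchsorted(rpt_s, centers - half, side="left")
    hi = np.searchsorted(rpt_s, centers + half, side="right")
    n_total = (hi - lo).astype(int)
    n_correct = (csum[hi] - csum[lo]).astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_total > 0, n_correct / np.maximum(n_total, 1), np.nan)
    ci_low, ci_high = clopper_pearson(n_correct, n_total, ci_level)

    return TachometricCurve(
        centers=centers,
        n_total=n_total,
        n_correct=n_correct,
        frac_correct=frac,
        ci_low=ci_low,
        ci_high=ci_high,
        bin_width=float(bin_width),
        ci_level=float(ci_level),
        meta=dict(meta or {}),
    )


def pool_curves(
    trial_sets: list[pd.DataFrame],
    bin_width: float = 31.0,
    bin_step: float = 1.0,
    grid: tuple[float, float] = (0.0, 300.0),
    ci_level: float = 0.95,
) -> TachometricCurve:
    """Curve of the pooled trials: pooling happens at the trial level.

    Identical to ``compute_curve`` on the concatenation of the sets; it is
    *not* an average of per-set curves.
    """
    pooled = pd.concat(trial_sets, ignore_index=True) if trial_sets else pd.DataFrame(
        {"rpt": [], "correct": []}
    )
    return compute_curve(pooled, bin_width, bin_step, grid, ci_level,
                         meta={"pooled_sets": len(trial_sets)})
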