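"""Sigmoid characterization of tachometric curves.

The model is a four-parameter logistic

    s(x) = B + (A - B) / (1 + exp(-(x - C) / D))

with baseline B, asymptote A, rise point C (the rpt at which s reaches the
midpoint between B and A) and slope scale D.  Fitting minimizes the *mean
absolute error* between model and empirical curve over the defined bins of
the evaluation range, using a derivative-free simplex search.  The baseline
is free (not pinned to 0.5) so that guessing biases are absorbed by B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .tachometric import TachometricCurve, compute_curve

logger = logging.getLogger("tachy")

D_MAX = 200.0  # slope-scale upper bound (ms); D is kept in (0, D_MAX]


class FitError(RuntimeError):
    """The curve cannot be fitted (too few defined bins)."""


@dataclass
class SigmoidFit:
    """Fitted parameters plus the achieved objective value."""

    A: float
    B: float
    C: float
    D: float
    mae: float
    rpt_fit_range: tuple[float, float] = (0.0, 300.0)
    n_bins: int = 0

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.A, self.B, self.C, self.D)

    @property
    def halfway(self) -> float:
        """Accuracy level at the rise point: (A + B) / 2."""
        return 0.5 * (self.A + self.B)


@dataclass
class FitQuality:
    """Modulation / fit-error gate deciding whether a rise point is reliable."""

    delta_s: float
    e: float
    ratio: float
    passes: bool
    threshold: float = 2.5


@dataclass
class BootstrapResult:
    n_reps: int
    param_samples: pd.DataFrame  # columns A, B, C, D; one row per successful rep
    ci95: dict                   # param -> (lo, hi), 2.5/97.5 percentiles
    n_degenerate: int = 0
    seed: int | None = None


def sigmoid_eval(x, params) -> np.ndarray | float:
    """Evaluate s(x) for params (A, B, C, D)."""
    A, B, C, D = params
    if D == 0:
        raise ValueError("D must be nonzero")
    return B + (A - B) * expit((np.asarray(x, dtype=float) - C) / D)


def sigmoid_inverse(y: float, params) -> float:
    """The rpt at which s(x) = y; requires y strictly between B and A."""
    A, B, C, D = params
    lo, hi = min(A, B), max(A, B)
    if not lo < y < hi:
        raise ValueError(f"level {y} outside open range ({lo}, {hi})")
    z = (y - B) / (A - B)
    return C + D * np.log(z / (1.0 - z))


def _pack(A, B, C, D):
    eps = 1e-9
    return np.array([
        logit(np.clip(A, eps, 1 - eps)),
        logit(np.clip(B, eps, 1 - eps)),
        C,
        logit(np.clip(D / D_MAX, eps, 1 - eps)),
    ])


def _unpack(theta):
    a, b, c, d = theta
    return (float(expit(a)), float(expit(b)), float(c), float(D_MAX * expit(d)))


def _auto_init(x: np.ndarray, f: np.ndarray) -> tuple[float, float, float, float]:
    """Heuristic start: baseline from early bins, asymptote from late bins."""
    early = f[x < 100]
    late = f[x > 250]
    B0 = float(np.mean(early)) if early.size else float(f[0])
    A0 = float(np.mean(late)) if late.size else float(f[-1])
    if abs(A0 - B0) < 1e-3:
        A0 = B0 + 0.1
    mid = 0.5 * (A0 + B0)
    above = np.nonzero(f >= mid if A0 > B0 else f <= mid)[0]
    C0 = float(x[above[0]]) if above.size else float(np.median(x))
    return A0, B0, C0, 25.0


def fit_sigmoid(
    curve: TachometricCurve,
    init: tuple[float, float, float, float] | None = None,
    rpt_range: tuple[float, float] = (0.0, 300.0),
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 2000,
) -> SigmoidFit:
    """Fit the four-parameter sigmoid by mean-absolute-error minimization.

    A Nelder-Mead simplex runs in a transformed space that keeps A and B in
    [0, 1] and D in (0, 200].  ``n_starts`` jittered initializations (seeded)
    are tried and the best objective kept; the winner is polished with one
    restart from its own solution.
    """
    in_range = (curve.centers >= rpt_range[0]) & (curve.centers <= rpt_range[1])
    mask = in_range & curve.defined
    x = curve.centers[mask]
    f = curve.frac_correct[mask]
    if x.size < 10:
        raise FitError(f"only {x.size} defined bins in {rpt_range}; need >= 10")

    def objective(theta):
        A, B, C, D = _unpack(theta)
        return float(np.mean(np.abs(B + (A - B) * expit((x - C) / D) - f)))

    base = init if init is not None else _auto_init(x, f)
    rng = np.random.default_rng(seed)
    starts = [np.asarray(base, dtype=float)]
    for _ in range(max(0, n_starts - 1)):
        A0, B0, C0, D0 = base
        starts.append(np.array([
            np.clip(A0 + rng.normal(0, 0.05), 0.01, 0.99),
            np.clip(B0 + rng.normal(0, 0.05), 0.01, 0.99),
            C0 + rng.normal(0, 15.0),
            np.clip(D0 * np.exp(rng.normal(0, 0.3)), 1.0, D_MAX - 1),
        ]))

    best_theta, best_val = None, np.inf
    opts = {"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-9}
    for s in starts:
        res = minimize(objective, _pack(*s), method="Nelder-Mead", options=opts)
        if res.fun < best_val:
            best_theta, best_val = res.x, res.fun
    # one polishing restart from the winner (restarted simplex)
    res = minimize(objective, best_theta, method="Nelder-Mead", options=opts)
    if res.fun < best_val:
        best_theta, best_val = res.x, res.fun

    A, B, C, D = _unpack(best_theta)
    return SigmoidFit(A=A, B=B, C=C, D=D, mae=float(best_val),
                      rpt_fit_range=tuple(rpt_range), n_bins=int(x.size))


def rise_point(fit: SigmoidFit) -> float:
    """The rpt at which the fitted curve reaches (A + B) / 2: parameter C."""
    return fit.C


def rpt_at_criterion(fit: SigmoidFit, theta: float = 0.7) -> float | None:
    """The rpt at which the fitted curve first exceeds ``theta``; None if never.

    Closed-form logistic inverse; defined only when B < theta < A (rising
    curve).  Returns None when the asymptote never exceeds the criterion.
    """
    if not 0 < theta < 1:
        raise ValueError("theta must lie in (0, 1)")
    if fit.A <= fit.B:      # non-rising fit: no first crossing
        return None
    if theta >= fit.A:
        return None
    if theta <= fit.B:      # already above criterion at all rpts
        return -np.inf
    return float(sigmoid_inverse(theta, fit.params))


def fit_quality(
    fit: SigmoidFit,
    curve: TachometricCurve,
    rpt_range: tuple[float, float] = (0.0, 300.0),
    threshold: float = 2.5,
) -> FitQuality:
    """Curve modulation (max - min of the fitted sigmoid over the range) and
    mean absolute fit error over defined bins; gate passes when the ratio
    exceeds ``threshold``."""
    in_range = (curve.centers >= rpt_range[0]) & (curve.centers <= rpt_range[1])
    grid = curve.centers[in_range]
    s = sigmoid_eval(grid, fit.params)
    delta_s = float(np.max(s) - np.min(s))

    mask = in_range & curve.defined
    e = float(np.mean(np.abs(sigmoid_eval(curve.centers[mask], fit.params)
                             - curve.frac_correct[mask])))
    if delta_s == 0:
        ratio = 0.0          # flat fit: no modulation, gate must fail
    elif e > 0:
        ratio = delta_s / e
    else:
        ratio = np.inf
    return FitQuality(delta_s=delta_s, e=e, ratio=float(ratio),
                      passes=bool(ratio > threshold), threshold=threshold)


def bootstrap_fit(
    trials: pd.DataFrame,
    n_reps: int = 1000,
    bin_width: float = 31.0,
    bin_step: float = 1.0,
    grid: tuple[float, float] = (0.0, 300.0),
    rpt_range: tuple[float, float] = (0.0, 300.0),
    seed: int = 0,
    min_modulation: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap of the sigmoid parameters.

    Each rep resamples the N trials with replacement, rebuilds the curve and
    refits (single start, initialized at the full-data fit).  Reps whose fit
    fails or is degenerate (modulation below ``min_modulation``) are counted
    and excluded from the percentiles.
    """
    rng = np.random.default_rng(seed)
    n = len(trials)
    base_curve = compute_curve(trials, bin_width, bin_step, grid)
    try:
        base_fit = fit_sigmoid(base_curve, rpt_range=rpt_range, seed=seed)
        base_init = base_fit.params
    except FitError:
        base_init = None

    rows = []
    n_degenerate = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n, size=n)
        resampled = trials.iloc[idx]
        curve = compute_curve(resampled, bin_width, bin_step, grid)
        try:
            fit = fit_sigmoid(curve, init=base_init, rpt_range=rpt_range,
                              n_starts=1, seed=0)
        except FitError:
            n_degenerate += 1
            continue
        if abs(fit.A - fit.B) < min_modulation:
            n_degenerate += 1
            continue
        rows.append(fit.params)

    samples = pd.DataFrame(rows, columns=["A", "B", "C", "D"])
    ci95 = {}
    for col in samples.columns:
        if len(samples):
            lo, hi = np.percentile(samples[col], [2.5, 97.5])
            ci95[col] = (float(lo), float(hi))
        else:
            ci95[col] = (np.nan, np.nan)
    if n_degenerate:
        logger.warning("bootstrap: %d of %d reps degenerate/failed", n_degenerate, n_reps)
    return BootstrapResult(n_reps=n_reps, param_samples=samples, ci95=ci95,
                           n_degenerate=n_degenerate, seed=seed)
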