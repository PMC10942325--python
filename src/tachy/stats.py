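"""Resampling and exact inference: paired permutation, randomization,
binomial, and correlation tests, plus ordinary least squares.

Monte-Carlo p-values use the +1 continuity correction
(p = (1 + #{|null| >= |obs|}) / (n_iter + 1)) so that p is never zero.
Whenever the null distribution can be enumerated exhaustively within the
iteration budget (2^n sign patterns for paired data, n! shuffles for
correlations), enumeration is used instead and the p-value is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    n_iterations: int = 0
    seed: int | None = None
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def paired_permutation_test(a, b, n_iter: int = 100_000, seed: int = 0,
                            force_monte_carlo: bool = False) -> TestResult:
    """Two-sided paired permutation test on mean(a - b) by random sign flips.

    Exhaustive over all 2^n sign patterns when that is within ``n_iter``;
    otherwise Monte Carlo with the +1 correction.  ``force_monte_carlo``
    disables the exhaustive shortcut (used to cross-validate the two paths).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    obs = float(np.mean(diffs))

    if 2 ** n <= n_iter and not force_monte_carlo:
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n), indexing="ij"))
        signs = signs.reshape(n, -1).T            # (2^n, n)
        null = (signs * diffs).mean(axis=1)
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        return TestResult(obs, p, n, "paired_permutation", int(2 ** n),
                          seed=None, exhaustive=True)

    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_iter, n))
    null = (signs * diffs).mean(axis=1)
    hits = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
    p = (1 + hits) / (n_iter + 1)
    return TestResult(obs, p, n, "paired_permutation", n_iter, seed=seed)


def randomization_test(a, b, n_iter: int = 100_000, seed: int = 0) -> TestResult:
    """Two-sided randomization test for unpaired samples on mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_iter):
        perm = rng.permutation(pooled)
        stat = perm[: a.size].mean() - perm[a.size:].mean()
        hits += abs(stat) >= abs(obs) - 1e-12
    p = (1 + hits) / (n_iter + 1)
    return TestResult(obs, p, a.size + b.size, "randomization", n_iter, seed=seed)


def binomial_test(k: int, n: int, p0: float = 0.5,
                  alternative: str = "two-sided") -> TestResult:
    """Exact binomial test.

    ``two-sided`` uses minimum-likelihood tail summation (the probability of
    every outcome no more likely than the observed one).  ``greater`` /
    ``less`` are single upper / lower tails.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    res = sps.binomtest(k, n, p0, alternative=alternative)
    return TestResult(float(k / n if n else np.nan), float(res.pvalue), n,
                      "binomial", 0, exhaustive=True)


def correlation_with_permutation(x, y, n_iter: int = 10_000, seed: int = 0) -> TestResult:
    """Pearson correlation with a two-sided permutation p-value (shuffle y).

    Exhaustive over all n! orderings when that is within ``n_iter``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length x, y with n >= 3")
    n = x.size
    obs = float(np.corrcoef(x, y)[0, 1])

    def _r(yy):
        return np.corrcoef(x, yy)[0, 1]

    if factorial(n) <= n_iter:
        null = np.array([_r(np.asarray(p)) for p in permutations(y)])
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        return TestResult(obs, p, n, "correlation_permutation", factorial(n),
                          seed=None, exhaustive=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_iter):
        hits += abs(_r(rng.permutation(y))) >= abs(obs) - 1e-12
    p = (1 + hits) / (n_iter + 1)
    return TestResult(obs, p, n, "correlation_permutation", n_iter, seed=seed)


def linear_regression(x, y) -> tuple[float, float, np.ndarray]:
    """Ordinary least squares y = slope * x + intercept.

    Returns (slope, intercept, predictions at the input x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length x, y with n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    pred = res.slope * x + res.intercept
    return float(res.slope), float(res.intercept), pred
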