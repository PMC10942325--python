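"""Headline behavioral metrics: exogenous capture, guessing bias, motor bias,
antisaccade processing-time cost, and four-range performance summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnalysisConfig, TrialFilter, apply_filter
from .sigmoid import SigmoidFit, sigmoid_inverse
from .tachometric import TachometricCurve, clopper_pearson, compute_curve

logger = logging.getLogger("tachy")

CAPTURE_WINDOW = (83.0, 124.0)    # ms, inclusive at both ends
GUESSING_MAX_RPT = 75.0           # ms, inclusive
TRANSITION_RANGE = (135.0, 200.0)  # [135, 200)
ASYMPTOTIC_MIN_RPT = 200.0        # inclusive

RANGES = {
    "G": lambda rpt: rpt <= GUESSING_MAX_RPT,
    "C": lambda rpt: (rpt >= CAPTURE_WINDOW[0]) & (rpt <= CAPTURE_WINDOW[1]),
    "T": lambda rpt: (rpt >= TRANSITION_RANGE[0]) & (rpt < TRANSITION_RANGE[1]),
    "A": lambda rpt: rpt >= ASYMPTOTIC_MIN_RPT,
}


@dataclass
class CaptureResult:
    """Fraction correct inside the exogenous response window, per trial type."""

    window: tuple[float, float]
    frac_correct_pro: float
    frac_correct_anti: float
    ci_pro: tuple[float, float]
    ci_anti: tuple[float, float]
    n_pro: int
    n_anti: int


@dataclass
class GuessBias:
    """Cue-directedness of uninformed choices (rpt <= 75 ms, pro + anti)."""

    n_toward_cue: int
    n_toward_noncue: int
    frac_toward_cue: float
    ci: tuple[float, float]


@dataclass
class ParticipantBiasCost:
    """Per-participant motor bias and antisaccade processing-time cost."""

    delta_rpt: float | None      # ms; None when the criterion is unattainable
    delta_bias: float            # B_pro - B_anti
    criterion_level: float       # max of the two halfway levels
    fit_pro: SigmoidFit
    fit_anti: SigmoidFit


def derive_capture_window(
    pairs: list[tuple[TachometricCurve, TachometricCurve]] | tuple,
    search_range: tuple[float, float] = (50.0, 200.0),
) -> tuple[float, float] | None:
    """Locate the exogenous response window from pro/anti curve pairs.

    For each (pro, anti) pair the anti curve is mirrored about 0.5; the
    window is the maximal contiguous run of bins, around the point of
    strongest joint deviation, where the pro and mirrored-anti curves deviate
    from 0.5 with the same sign — i.e. where the response to the brighter
    stimulus is consistently above that to the dimmer one.  The run is
    bounded by either curve crossing 0.5.  With several pairs the windows are
    intersected.  Returns None when no such window exists.
    """
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], TachometricCurve):
        pairs = [pairs]

    windows = []
    for pro, anti in pairs:
        if not np.array_equal(pro.centers, anti.centers):
            raise ValueError("pro and anti curves must share the same grid")
        centers = pro.centers
        in_range = (centers >= search_range[0]) & (centers <= search_range[1])
        d_pro = pro.frac_correct - 0.5
        d_mir = (1.0 - anti.frac_correct) - 0.5
        ok = (
            in_range
            & np.isfinite(d_pro)
            & np.isfinite(d_mir)
            & (np.sign(d_pro) == np.sign(d_mir))
            & (d_pro != 0)
        )
        if not ok.any():
            logger.info("derive_capture_window: no joint deviation in range")
            return None
        joint = np.where(ok, np.abs(d_pro + d_mir), -np.inf)
        peak = int(np.argmax(joint))
        lo = peak
        while lo - 1 >= 0 and ok[lo - 1]:
            lo -= 1
        hi = peak
        while hi + 1 < ok.size and ok[hi + 1]:
            hi += 1
        windows.append((float(centers[lo]), float(centers[hi])))

    w_lo = max(w[0] for w in windows)
    w_hi = min(w[1] for w in windows)
    if w_lo >= w_hi:
        logger.info("derive_capture_window: windows do not intersect: %s", windows)
        return None
    return (w_lo, w_hi)


def capture_fraction(
    trials: pd.DataFrame,
    window: tuple[float, float] = CAPTURE_WINDOW,
    ci_level: float = 0.95,
) -> CaptureResult:
    """Fraction correct within the (closed) capture window, per trial type."""
    inside = apply_filter(trials, TrialFilter(rpt_min=window[0], rpt_max=window[1]))
    out = {}
    for tt in ("pro", "anti"):
        sub = inside[inside["trial_type"] == tt]
        n = len(sub)
        k = int(sub["correct"].sum())
        frac = k / n if n else np.nan
        lo, hi = clopper_pearson(np.array([k]), np.array([n]), ci_level)
        out[tt] = (frac, (float(lo[0]), float(hi[0])), n)
    return CaptureResult(
        window=tuple(window),
        frac_correct_pro=out["pro"][0], frac_correct_anti=out["anti"][0],
        ci_pro=out["pro"][1], ci_anti=out["anti"][1],
        n_pro=out["pro"][2], n_anti=out["anti"][2],
    )


def guess_bias(
    trials: pd.DataFrame,
    max_rpt: float = GUESSING_MAX_RPT,
    ci_level: float = 0.95,
) -> GuessBias:
    """Fraction of short-rpt choices (pro and anti combined) toward the cue.

    "Toward the cue" is side equality with the block's cue location, so an
    anti-trial error counts toward the cue.
    """
    guesses = apply_filter(trials, TrialFilter(urgency="urgent_only", rpt_max=max_rpt))
    toward = int((guesses["choice_side"] == guesses["cue_side"]).sum())
    away = len(guesses) - toward
    n = toward + away
    frac = toward / n if n else np.nan
    lo, hi = clopper_pearson(np.array([toward]), np.array([n]), ci_level)
    return GuessBias(n_toward_cue=toward, n_toward_noncue=away,
                     frac_toward_cue=frac, ci=(float(lo[0]), float(hi[0])))


def antisaccade_cost(fit_pro: SigmoidFit, fit_anti: SigmoidFit) -> ParticipantBiasCost:
    """Motor bias and antisaccade cost from a participant's pro/anti fits.

    The shared criterion is the higher of the two halfway levels
    (A + B) / 2; the cost is the anti-minus-pro difference of the rpts at
    which the fitted curves attain it.  The bias is B_pro - B_anti.  When the
    criterion exceeds one curve's asymptote the cost is undefined (None).
    """
    criterion = max(fit_pro.halfway, fit_anti.halfway)
    delta_bias = fit_pro.B - fit_anti.B

    def _at(fit: SigmoidFit) -> float | None:
        if not (fit.B < criterion < fit.A):
            return None
        return float(sigmoid_inverse(criterion, fit.params))

    rpt_pro = _at(fit_pro)
    rpt_anti = _at(fit_anti)
    delta_rpt = None if rpt_pro is None or rpt_anti is None else rpt_anti - rpt_pro
    return ParticipantBiasCost(
        delta_rpt=delta_rpt, delta_bias=float(delta_bias),
        criterion_level=float(criterion), fit_pro=fit_pro, fit_anti=fit_anti,
    )


def range_summary(trials: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Fraction correct per participant x experiment x trial type x rpt range.

    Ranges: G (rpt <= 75), C (83 <= rpt <= 124), T (135 <= rpt < 200),
    A (rpt >= 200); trials in the gaps between ranges belong to none.
    Returns a tidy frame with columns participant, experiment, trial_type,
    range, n, n_correct, frac_correct.
    """
    cfg = config or AnalysisConfig()
    urgent = apply_filter(trials, TrialFilter(urgency="urgent_only"))
    ranges = {
        "G": lambda r: r <= cfg.guessing_max_rpt,
        "C": lambda r: (r >= cfg.capture_window[0]) & (r <= cfg.capture_window[1]),
        "T": lambda r: (r >= cfg.transition_range[0]) & (r < cfg.transition_range[1]),
        "A": lambda r: r >= cfg.asymptotic_min_rpt,
    }
    rows = []
    grouped = urgent.groupby(["participant", "experiment", "trial_type"], sort=True)
    for (pid, exp, tt), sub in grouped:
        rpt = sub["rpt"].to_numpy()
        corr = sub["correct"].to_numpy(dtype=bool)
        for name, pred in ranges.items():
            m = pred(rpt)
            n = int(m.sum())
            k = int(corr[m].sum())
            rows.append({
                "participant": pid, "experiment": exp, "trial_type": tt,
                "range": name, "n": n, "n_correct": k,
                "frac_correct": k / n if n else np.nan,
            })
    return pd.DataFrame(rows)


def bias_cost_differences(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-participant pro-minus-anti accuracy differences in the T and G
    ranges (pooled over experiments), the inputs to the bias-cost regression."""
    pooled = (
        summary.groupby(["participant", "trial_type", "range"])[["n", "n_correct"]]
        .sum()
        .reset_index()
    )
    pooled["frac"] = pooled["n_correct"] / pooled["n"].where(pooled["n"] > 0)
    wide = pooled.pivot_table(index="participant", columns=["trial_type", "range"],
                              values="frac")
    out = pd.DataFrame(index=wide.index)
    for rng in ("G", "T"):
        out[f"diff_{rng}"] = wide[("pro", rng)] - wide[("anti", rng)]
    return out.reset_index()


def reliable_performers(
    trials: pd.DataFrame,
    threshold: float = 0.7,
) -> list[str]:
    """Participants exceeding ``threshold`` fraction correct in *easy* trials
    (gap < 0) in every experiment x trial-type cell (8 cells when all four
    experiments are present).  The inequality is strict."""
    easy = apply_filter(trials, TrialFilter(urgency="easy_only"))
    if easy.empty:
        return []
    cells = (
        easy.groupby(["participant", "experiment", "trial_type"])["correct"]
        .agg(["mean", "count"])
        .reset_index()
    )
    n_cells = cells.groupby("participant").size()
    expected = len(easy["experiment"].unique()) * len(easy["trial_type"].unique())
    passing = cells.groupby("participant")["mean"].agg(lambda m: bool((m > threshold).all()))
    keep = [
        str(p) for p in passing.index
        if passing[p] and n_cells[p] == expected
    ]
    return sorted(keep)
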