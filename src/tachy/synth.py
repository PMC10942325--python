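"""Synthetic urgent-choice trials and eye traces with known ground truth.

The generative accuracy model composes three ingredients observed in urgent
pro/antisaccade data:

* a guessing baseline at short rpt, biased toward the cued side — pro
  baseline = ``baseline_bias``, anti baseline = 1 - ``baseline_bias``;
* a transient, salience-driven capture deflection modeled as a Gaussian bump
  centered near 100 ms whose sign depends on which stimulus is brighter and
  on the trial type;
* a sigmoidal, goal-driven rise toward the asymptote whose rise point is
  later for anti than for pro trials (default separation 30 ms).

Correctness is sampled first (Bernoulli at the composed accuracy) and the
chosen side derived from it, so the planted accuracy function is exactly the
one the data obey.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GAP_SET
from .saccades import EyeTrace
from .sigmoid import sigmoid_eval

URGENT_GAPS = tuple(g for g in GAP_SET if g >= 0)
BLOCK_SIZE = 150  # trials per block; cue side is fixed within a block


@dataclass
class GenerativeParams:
    """Ground-truth accuracy model p(correct | rpt, trial type)."""

    baseline_bias: float = 0.5       # fraction of guesses toward the cue
    capture_amp: float = 0.0         # magnitude of the luminance-driven bump
    capture_center: float = 100.0    # ms
    capture_halfwidth: float = 20.0  # Gaussian sigma, ms
    endo_A: float = 0.9              # asymptotic accuracy
    endo_C_pro: float = 165.0        # pro rise point, ms
    endo_C_anti: float = 195.0       # anti rise point, ms
    endo_D: float = 20.0             # slope scale, ms
    rt_mean: float = 280.0
    rt_sd: float = 60.0
    rt_bounds: tuple[float, float] = (100.0, 600.0)
    gap_set: tuple[float, ...] = URGENT_GAPS
    gap_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.baseline_bias <= 1:
            raise ValueError("baseline_bias must lie in [0, 1]")
        if not 0 <= self.endo_A <= 1:
            raise ValueError("endo_A must lie in [0, 1]")
        # No clipping allowed: the composed accuracy must stay inside [0, 1]
        # for every trial type under either capture sign.  The composition is
        # smooth on scales >= endo_D / halfwidth, so a fine grid is decisive.
        grid = np.arange(0.0, 600.0, 0.5)
        bump = self.capture_amp * np.exp(
            -((grid - self.capture_center) ** 2) / (2.0 * self.capture_halfwidth ** 2)
        )
        for B, C in ((self.baseline_bias, self.endo_C_pro),
                     (1.0 - self.baseline_bias, self.endo_C_anti)):
            sig = B + (self.endo_A - B) / (1.0 + np.exp(-(grid - C) / self.endo_D))
            for signed in (sig + bump, sig - bump):
                if signed.min() < -1e-12 or signed.max() > 1 + 1e-12:
                    raise ValueError(
                        f"capture_amp {self.capture_amp} pushes accuracy outside "
                        f"[0, 1] (range [{signed.min():.3f}, {signed.max():.3f}])"
                    )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LuminanceCondition:
    """Experiment-level luminance assignment and its implied capture sign.

    Experiments: 1 = both bright, 2 = both dim (no net capture);
    3 = bright cue (capture toward the cue); 4 = bright non-cue (capture
    toward the non-cue).
    """

    experiment: int
    cue_luminance: str
    noncue_luminance: str

    HIGH_CD = 48.0
    LOW_CD = 0.25

    @classmethod
    def from_experiment(cls, experiment: int) -> "LuminanceCondition":
        table = {
            1: ("high", "high"),
            2: ("low", "low"),
            3: ("high", "low"),
            4: ("low", "high"),
        }
        if experiment not in table:
            raise ValueError(f"experiment must be 1-4, got {experiment}")
        cue, noncue = table[experiment]
        return cls(experiment=experiment, cue_luminance=cue, noncue_luminance=noncue)

    @property
    def capture_sign_toward_cue(self) -> int:
        """+1 capture toward cue, -1 toward non-cue, 0 balanced."""
        if self.cue_luminance == self.noncue_luminance:
            return 0
        return 1 if self.cue_luminance == "high" else -1


def accuracy_function(
    rpt, params: GenerativeParams, trial_type: str,
    condition: LuminanceCondition | None = None,
) -> np.ndarray | float:
    """Planted p(correct | rpt) for one trial type under one condition.

    Capture toward the cue raises pro accuracy and lowers anti accuracy
    (and vice versa for capture toward the non-cue), mirroring the opposite
    early deflections of the two curve families.
    """
    if trial_type not in ("pro", "anti"):
        raise ValueError(f"trial_type must be pro/anti, got {trial_type!r}")
    rpt = np.asarray(rpt, dtype=float)
    if trial_type == "pro":
        B, C = params.baseline_bias, params.endo_C_pro
        type_sign = 1.0
    else:
        B, C = 1.0 - params.baseline_bias, params.endo_C_anti
        type_sign = -1.0

    p = sigmoid_eval(rpt, (params.endo_A, B, C, params.endo_D))
    toward_cue = condition.capture_sign_toward_cue if condition is not None else 0
    if params.capture_amp != 0.0 and toward_cue != 0:
        bump = np.exp(-((rpt - params.capture_center) ** 2)
                      / (2.0 * params.capture_halfwidth ** 2))
        p = p + type_sign * toward_cue * params.capture_amp * bump
    return p


def _sample_rt(rng: np.random.Generator, n: int, params: GenerativeParams) -> np.ndarray:
    lo, hi = params.rt_bounds
    out = np.empty(n)
    filled = 0
    while filled < n:  # rejection sampling of the truncated normal
        draw = rng.normal(params.rt_mean, params.rt_sd, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled: filled + keep.size] = keep
        filled += keep.size
    return out


def generate_trials(
    params: GenerativeParams,
    condition: LuminanceCondition | int,
    n: int,
    seed: int = 0,
    participant: str = "sim01",
) -> pd.DataFrame:
    """Sample ``n`` trials from the planted model; reproducible under seed.

    Per trial: gap from the (urgent) gap set, RT from a truncated normal,
    rpt = rt - gap, trial type at random, correctness ~ Bernoulli(planted
    accuracy), and the chosen side derived from correctness.  The cue side
    is fixed within each 150-trial block and alternates across blocks.
    """
    if isinstance(condition, int):
        condition = LuminanceCondition.from_experiment(condition)
    if n == 0:
        return pd.DataFrame(
            columns=["participant", "experiment", "trial_type", "cue_side",
                     "gap", "rt", "choice_side", "correct", "excluded",
                     "exclusion_reason", "rpt"]
        )
    rng = np.random.default_rng(seed)

    gaps = np.asarray(params.gap_set, dtype=float)
    weights = params.gap_weights
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    gap = rng.choice(gaps, size=n, p=weights)
    rt = _sample_rt(rng, n, params)
    rpt = rt - gap
    trial_type = np.where(rng.random(n) < 0.5, "pro", "anti")

    block = np.arange(n) // BLOCK_SIZE
    first = rng.integers(0, 2)
    cue_side = np.where((block + first) % 2 == 0, "left", "right")

    p = np.empty(n)
    for tt in ("pro", "anti"):
        m = trial_type == tt
        p[m] = accuracy_function(rpt[m], params, tt, condition)
    correct = rng.random(n) < p

    other = np.where(cue_side == "left", "right", "left")
    # pro: correct means toward cue; anti: correct means toward non-cue
    choice = np.where(
        (trial_type == "pro") == correct, cue_side, other
    )

    df = pd.DataFrame(
        {
            "participant": participant,
            "experiment": condition.experiment,
            "trial_type": trial_type,
            "cue_side": cue_side,
            "gap": gap,
            "rt": rt,
            "choice_side": choice,
            "correct": correct,
            "excluded": False,
            "exclusion_reason": "none",
        }
    )
    df["rpt"] = df["rt"] - df["gap"]
    return df


# ---------------------------------------------------------------------------
# eye-trace synthesis

@dataclass
class TraceKinematics:
    """Knobs for synthetic 1 kHz gaze traces."""

    sample_rate_hz: float = 1000.0
    amplitude_deg: float = 8.0
    saccade_duration_ms: float = 50.0
    noise_sd_deg: float = 0.0
    pre_ms: float = 300.0    # recording before the go signal
    post_ms: float = 300.0   # recording after saccade end


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def threshold_crossing_delay(
    amplitude_deg: float, duration_ms: float, threshold_deg_s: float = 40.0
) -> float | None:
    """Time (ms) after kinematic onset at which the analytic minimum-jerk
    speed first exceeds ``threshold_deg_s``; None if the peak never does.

    Closed form: speed(tau) = 30 (A / T) [tau (1 - tau)]^2, so the crossing
    solves tau (1 - tau) = sqrt(threshold * T / (30 A)).
    """
    T_s = duration_ms / 1000.0
    s = np.sqrt(threshold_deg_s * T_s / (30.0 * amplitude_deg))
    if 4.0 * s > 1.0:
        return None
    tau = (1.0 - np.sqrt(1.0 - 4.0 * s)) / 2.0
    return float(tau * duration_ms)


def generate_trace(
    trial: pd.Series | dict,
    kinematics: TraceKinematics | None = None,
    seed: int = 0,
    blink: tuple[float, float] | None = None,
) -> tuple[EyeTrace, dict]:
    """Synthesize the gaze trace for one trial; returns (trace, truth).

    The eye fixates at the origin, then launches a minimum-jerk horizontal
    saccade of ``amplitude_deg`` toward ``choice_side`` at
    ``go_time + rt``.  ``blink`` marks an interval of invalid samples.
    ``truth`` records the kinematic onset (``onset_ms``) and the time the
    analytic speed profile first exceeds 40 deg/s
    (``threshold_crossing_ms``) — the earliest instant a threshold detector
    can respond, which is a few ms after the kinematic onset.
    """
    k = kinematics or TraceKinematics()
    t = dict(trial) if not isinstance(trial, dict) else trial
    rt = float(t["rt"])
    gap = float(t["gap"])
    sign = 1.0 if t["choice_side"] == "right" else -1.0

    dt = 1000.0 / k.sample_rate_hz
    go_time = k.pre_ms
    cue_on_time = go_time + gap
    onset = go_time + rt
    end = onset + k.saccade_duration_ms
    t_axis = np.arange(0.0, end + k.post_ms + dt / 2, dt)

    x = sign * k.amplitude_deg * minimum_jerk((t_axis - onset) / k.saccade_duration_ms)
    y = np.zeros_like(t_axis)
    if k.noise_sd_deg > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0, k.noise_sd_deg, t_axis.size)
        y = y + rng.normal(0, k.noise_sd_deg, t_axis.size)

    valid = np.ones(t_axis.size, dtype=bool)
    if blink is not None:
        valid[(t_axis >= blink[0]) & (t_axis <= blink[1])] = False

    trace = EyeTrace(
        t=t_axis, x=x, y=y, valid=valid,
        go_time=go_time, cue_on_time=cue_on_time,
        cue_side=str(t["cue_side"]), trial_type=str(t["trial_type"]),
        gap=gap, target_x=sign * k.amplitude_deg,
    )
    delay = threshold_crossing_delay(k.amplitude_deg, k.saccade_duration_ms)
    truth = {
        "onset_ms": onset,
        "threshold_crossing_ms": None if delay is None else onset + delay,
    }
    return trace, truth
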