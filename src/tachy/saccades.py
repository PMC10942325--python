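"""Saccade detection and trial scoring from raw gaze traces.

Detection uses a speed threshold (default 40 deg/s, strict inequality) on a
central-difference velocity estimate computed after light moving-average
smoothing of position.  The scored saccade is the first threshold crossing
after the go signal; its end is the first later sample back below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VELOCITY_THRESHOLD = 40.0      # deg/s
NEAR_VERTICAL_DEG = 60.0       # exclusion: > 60 deg off the horizontal axis
BLINK_PAD_MS = 25.0
SMOOTH_SAMPLES = 5             # moving-average window for position


@dataclass
class EyeTrace:
    """Uniformly sampled gaze positions for one trial (nominal 1 kHz)."""

    t: np.ndarray                  # ms, strictly increasing, uniform
    x: np.ndarray                  # deg
    y: np.ndarray                  # deg
    go_time: float                 # fixation-offset time, ms
    cue_on_time: float             # stimulus-onset time, ms
    cue_side: str                  # "left" | "right"
    trial_type: str = "pro"
    gap: float = 0.0
    target_x: float = 8.0          # deg; choice targets at +-8 horizontally
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        dt = np.diff(self.t)
        if self.t.size < 3 or np.any(dt <= 0):
            raise ValueError("t must be strictly increasing with >= 3 samples")
        if np.ptp(dt) > 1e-3:  # 1 us tolerance on uniformity
            raise ValueError("non-uniform sampling")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class SaccadeEvent:
    onset_time: float       # ms
    end_time: float         # ms
    direction_deg: float    # signed angle from horizontal, deg
    amplitude: float        # deg, Euclidean onset -> end
    choice_side: str        # "left" | "right"


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return a
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, a[0]), a, np.full(window - 1 - pad, a[-1])])
    return np.convolve(padded, kernel, mode="valid")


def eye_speed(trace: EyeTrace, smooth_samples: int = SMOOTH_SAMPLES) -> np.ndarray:
    """Speed (deg/s) by central differences on smoothed position."""
    xs = _smooth(trace.x, smooth_samples)
    ys = _smooth(trace.y, smooth_samples)
    dt_s = trace.dt / 1000.0
    vx = np.gradient(xs, dt_s)
    vy = np.gradient(ys, dt_s)
    return np.hypot(vx, vy)


def detect_saccade(
    trace: EyeTrace,
    velocity_threshold: float = VELOCITY_THRESHOLD,
    smooth_samples: int = SMOOTH_SAMPLES,
) -> SaccadeEvent | None:
    """First saccade after the go signal, or None if speed never crosses.

    Onset is the first sample after ``go_time`` with speed strictly above the
    threshold; the end is the first later sample with speed back below it
    (trace end if it never returns).  Direction and amplitude are taken from
    the onset -> end displacement.
    """
    if velocity_threshold <= 0:
        raise ValueError("velocity_threshold must be > 0")
    speed = eye_speed(trace, smooth_samples)
    after = trace.t > trace.go_time
    above = after & (speed > velocity_threshold)
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    i0 = int(idx[0])

    below = np.nonzero(speed[i0 + 1:] < velocity_threshold)[0]
    i1 = int(i0 + 1 + below[0]) if below.size else trace.t.size - 1

    dx = trace.x[i1] - trace.x[i0]
    dy = trace.y[i1] - trace.y[i0]
    direction = float(np.degrees(np.arctan2(dy, dx)))
    return SaccadeEvent(
        onset_time=float(trace.t[i0]),
        end_time=float(trace.t[i1]),
        direction_deg=direction,
        amplitude=float(np.hypot(dx, dy)),
        choice_side="right" if dx >= 0 else "left",
    )


def detect_blinks(trace: EyeTrace, pad_ms: float = BLINK_PAD_MS) -> list[tuple[float, float]]:
    """Intervals of missing/invalid samples, padded by ``pad_ms`` on each side."""
    invalid = ~trace.valid | ~np.isfinite(trace.x) | ~np.isfinite(trace.y)
    if not invalid.any():
        return []
    edges = np.diff(invalid.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if invalid[0]:
        starts.insert(0, 0)
    if invalid[-1]:
        ends.append(invalid.size - 1)
    return [
        (float(trace.t[s] - pad_ms), float(trace.t[e] + pad_ms))
        for s, e in zip(starts, ends)
    ]


def score_trial(
    event: SaccadeEvent | None,
    trace: EyeTrace,
    participant: str = "unknown",
    experiment: int = 1,
    min_amplitude: float | None = None,
    blink_pad_ms: float = BLINK_PAD_MS,
) -> dict:
    """Score one trial from its detected saccade; returns a canonical row.

    rt = onset - go_time, rpt = onset - cue_on_time (= rt - gap).  The choice
    is the horizontal direction of the first saccade; correctness follows the
    pro/anti rule.  Exclusions: no saccade (abort), blink overlapping
    [go, onset], or direction beyond +-60 deg of horizontal (near-vertical).
    Completed trials are retained even when the RT deadline was missed.
    ``min_amplitude`` (off by default) optionally drops small saccades.
    """
    base = {
        "participant": participant,
        "experiment": experiment,
        "trial_type": trace.trial_type,
        "cue_side": trace.cue_side,
        "gap": float(trace.cue_on_time - trace.go_time),
        "rt": np.nan,
        "choice_side": "left",
        "correct": False,
        "excluded": True,
        "exclusion_reason": "abort",
    }
    if event is None:
        return base

    rt = event.onset_time - trace.go_time
    choice = event.choice_side
    correct = (choice == trace.cue_side) == (trace.trial_type == "pro")
    row = dict(base, rt=float(rt), choice_side=choice, correct=bool(correct),
               excluded=False, exclusion_reason="none")

    for b0, b1 in detect_blinks(trace, blink_pad_ms):
        if b0 <= event.onset_time and b1 >= trace.go_time:
            row.update(excluded=True, exclusion_reason="blink")
            return row

    off_horizontal = min(abs(event.direction_deg), 180.0 - abs(event.direction_deg))
    if off_horizontal > NEAR_VERTICAL_DEG:
        row.update(excluded=True, exclusion_reason="near_vertical")
        return row

    if min_amplitude is not None and event.amplitude < min_amplitude:
        row.update(excluded=True, exclusion_reason="abort")
    return row


def detect_and_score(
    traces: list[EyeTrace],
    participant: str = "unknown",
    experiment: int = 1,
    velocity_threshold: float = VELOCITY_THRESHOLD,
    min_amplitude: float | None = None,
) -> pd.DataFrame:
    """Run detection + scoring over a batch of traces into a canonical table."""
    rows = []
    for trace in traces:
        event = detect_saccade(trace, velocity_threshold)
        rows.append(score_trial(event, trace, participant, experiment, min_amplitude))
    df = pd.DataFrame(rows)
    df["rpt"] = df["rt"] - df["gap"]
    return df
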