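"""Canonical trial tables: schema, CSV round-trip, filtering, configuration.

The canonical table is a :class:`pandas.DataFrame` with one row per completed
trial and the columns listed in :data:`CANONICAL_COLUMNS`.  All downstream
stages (curves, fits, metrics) consume these tables; nothing downstream ever
mutates them.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tachy")

#: Permitted gap durations (ms): negative gaps are easy (non-urgent) trials.
GAP_SET = (-200, -100, 0, 75, 100, 125, 150, 175, 200, 250, 350)

EXPERIMENTS = (1, 2, 3, 4)
TRIAL_TYPES = ("pro", "anti")
SIDES = ("left", "right")
EXCLUSION_REASONS = ("none", "abort", "blink", "near_vertical")

CANONICAL_COLUMNS = (
    "participant",
    "experiment",
    "trial_type",
    "cue_side",
    "gap",
    "rt",
    "choice_side",
    "correct",
    "excluded",
    "exclusion_reason",
)

#: Tolerance (ms) for a stored rpt column disagreeing with rt - gap.
RPT_TOLERANCE_MS = 0.5


class SchemaError(ValueError):
    """The input table does not match the canonical trial schema."""


class IntegrityError(ValueError):
    """The input table violates a definitional invariant (e.g. rpt != rt - gap)."""


@dataclass(frozen=True)
class Trial:
    """One completed urgent-choice trial."""

    participant: str
    experiment: int
    trial_type: str
    cue_side: str
    gap: float
    rt: float
    choice_side: str
    correct: bool
    excluded: bool = False
    exclusion_reason: str = "none"

    @property
    def rpt(self) -> float:
        """Raw processing time: rt - gap (definitional, always recomputed)."""
        return self.rt - self.gap

    @property
    def toward_cue(self) -> bool:
        return self.choice_side == self.cue_side


@dataclass(frozen=True)
class TrialFilter:
    """Declarative trial selection.  Filters select rows; they never mutate.

    ``urgency``: ``"urgent_only"`` keeps gap >= 0, ``"easy_only"`` keeps
    gap < 0, ``"all"`` keeps both.  Bounds on rpt are inclusive at both ends.
    Excluded trials are dropped unless ``keep_excluded`` is set.
    """

    urgency: str = "all"
    rpt_min: float | None = None
    rpt_max: float | None = None
    trial_types: tuple[str, ...] | None = None
    experiments: tuple[int, ...] | None = None
    participants: tuple[str, ...] | None = None
    keep_excluded: bool = False

    def __post_init__(self) -> None:
        if self.urgency not in ("urgent_only", "easy_only", "all"):
            raise ValueError(f"unknown urgency mode: {self.urgency!r}")

    def conjunction(self, other: "TrialFilter") -> "TrialFilter":
        """The single filter equivalent to applying self then other."""

        def _isect(a, b):
            if a is None:
                return b
            if b is None:
                return a
            return tuple(v for v in a if v in b)

        urg = {("all",): "all"}
        modes = {self.urgency, other.urgency}
        if modes == {"urgent_only", "easy_only"}:
            # contradictory: selects nothing; encode via impossible rpt bound
            return dataclasses.replace(self, urgency="urgent_only", rpt_min=np.inf)
        urgency = "all" if modes == {"all"} else (modes - {"all"}).pop()

        def _max(a, b):
            return b if a is None else a if b is None else max(a, b)

        def _min(a, b):
            return b if a is None else a if b is None else min(a, b)

        return TrialFilter(
            urgency=urgency,
            rpt_min=_max(self.rpt_min, other.rpt_min),
            rpt_max=_min(self.rpt_max, other.rpt_max),
            trial_types=_isect(self.trial_types, other.trial_types),
            experiments=_isect(self.experiments, other.experiments),
            participants=_isect(self.participants, other.participants),
            keep_excluded=self.keep_excluded and other.keep_excluded,
        )


URGENT = TrialFilter(urgency="urgent_only")
EASY = TrialFilter(urgency="easy_only")


@dataclass
class AnalysisConfig:
    """Analysis-wide parameters; defaults reproduce the published settings."""

    bin_width_aggregate: float = 31.0
    bin_width_single: float = 41.0
    bin_step: float = 1.0
    ci_level: float = 0.95
    criterion_theta: float = 0.7
    performance_criterion: float = 0.7
    modulation_ratio_threshold: float = 2.5
    capture_window: tuple[float, float] = (83.0, 124.0)
    guessing_max_rpt: float = 75.0
    transition_range: tuple[float, float] = (135.0, 200.0)  # [135, 200)
    asymptotic_min_rpt: float = 200.0
    fit_rpt_range: tuple[float, float] = (0.0, 300.0)
    n_bootstrap: int = 1000
    n_permutations: int = 100_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.capture_window, self.transition_range, self.fit_rpt_range):
            if not lo < hi:
                raise ValueError(f"window bounds must satisfy min < max, got ({lo}, {hi})")
        if not 0 < self.criterion_theta < 1:
            raise ValueError("criterion_theta must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for key in ("capture_window", "transition_range", "fit_rpt_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("capture_window", "transition_range", "fit_rpt_range"):
            d[key] = list(d[key])
        return d


def validate_trials(df: pd.DataFrame, *, source: str = "<table>") -> list[str]:
    """Return a list of row-level problems ("line N: message"); [] if clean.

    Line numbers are 1-based data-row numbers (header not counted).
    """
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.experiment not in EXPERIMENTS:
            problems.append(f"line {i}: experiment {row.experiment!r} not in 1-4")
        if row.trial_type not in TRIAL_TYPES:
            problems.append(f"line {i}: trial_type {row.trial_type!r} not pro/anti")
        if row.cue_side not in SIDES or row.choice_side not in SIDES:
            problems.append(f"line {i}: side must be left/right")
        if row.gap not in GAP_SET:
            problems.append(f"line {i}: gap {row.gap!r} not in permitted set")
        if not (isinstance(row.rt, (int, float)) and np.isfinite(row.rt) and row.rt >= 0):
            problems.append(f"line {i}: rt {row.rt!r} must be a finite number >= 0")
        if row.exclusion_reason not in EXCLUSION_REASONS:
            problems.append(f"line {i}: unknown exclusion_reason {row.exclusion_reason!r}")
    if problems:
        logger.warning("%s: %d malformed rows", source, len(problems))
    return problems


def check_correctness(df: pd.DataFrame) -> pd.Series:
    """Recompute correctness from sides: pro -> choice == cue, anti -> choice != cue."""
    pro = df["trial_type"] == "pro"
    same = df["choice_side"] == df["cue_side"]
    return (pro & same) | (~pro & ~same)


_DTYPES = {
    "participant": str,
    "experiment": int,
    "trial_type": str,
    "cue_side": str,
    "gap": float,
    "rt": float,
    "choice_side": str,
    "correct": bool,
    "excluded": bool,
    "exclusion_reason": str,
}


def read_trials(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Read a canonical trial CSV.

    Parameters
    ----------
    path:
        CSV file with header ``participant,experiment,trial_type,cue_side,
        gap,rt,choice_side,correct,excluded,exclusion_reason``.  An ``rpt``
        column, if present, is checked against rt - gap and then recomputed.
    column_map:
        Adapter hook mapping external column names onto canonical ones
        (``{"external_name": "canonical_name"}``), applied before validation.
    strict:
        If True, raise :class:`SchemaError` on missing columns and
        :class:`IntegrityError` on an rpt mismatch beyond 0.5 ms.  Malformed
        *rows* never raise; they are dropped and reported.

    Returns
    -------
    (trials, problems):
        The clean rows (with a recomputed ``rpt`` column) and the list of
        row-level problem strings for the dropped rows.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype={"participant": str})
    if column_map:
        raw = raw.rename(columns=dict(column_map))

    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        msg = f"{path.name}: missing required column(s): {', '.join(missing)}"
        if strict:
            raise SchemaError(msg)
        logger.error(msg)
        for col in missing:
            raw[col] = {"correct": False, "excluded": False,
                        "exclusion_reason": "none"}.get(col, np.nan)

    for col in ("correct", "excluded"):
        if col in raw.columns and raw[col].dtype == object:
            raw[col] = raw[col].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )

    problems = validate_trials(raw[list(CANONICAL_COLUMNS)], source=path.name)
    bad_lines = {int(p.split(":")[0].split()[1]) for p in problems}
    keep = [i for i in range(len(raw)) if (i + 1) not in bad_lines]
    df = raw.iloc[keep].reset_index(drop=True)

    recomputed = df["rt"].astype(float) - df["gap"].astype(float)
    if "rpt" in df.columns:
        delta = (df["rpt"].astype(float) - recomputed).abs()
        if (delta > RPT_TOLERANCE_MS).any():
            n_bad = int((delta > RPT_TOLERANCE_MS).sum())
            msg = f"{path.name}: stored rpt deviates from rt - gap by >0.5 ms in {n_bad} rows"
            if strict:
                raise IntegrityError(msg)
            logger.error(msg)
    df = df.astype({k: v for k, v in _DTYPES.items() if k in df.columns})
    df["rpt"] = df["rt"] - df["gap"]

    logger.info(
        "read %s: %d rows kept, %d malformed, %d flagged excluded",
        path.name, len(df), len(problems), int(df["excluded"].sum()),
    )
    return df[list(CANONICAL_COLUMNS) + ["rpt"]], problems


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical trial CSV (round-trips bit-exactly through read_trials)."""
    out = df.copy()
    out["rpt"] = out["rt"] - out["gap"]
    out[list(CANONICAL_COLUMNS) + ["rpt"]].to_csv(path, index=False)


def apply_filter(df: pd.DataFrame, f: TrialFilter) -> pd.DataFrame:
    """Select the rows satisfying every clause of ``f``; order preserved.

    Unless ``f.keep_excluded``, rows with ``excluded=True`` are dropped (the
    abort/blink/near-vertical exclusions).
    """
    mask = pd.Series(True, index=df.index)
    if not f.keep_excluded and "excluded" in df.columns:
        mask &= ~df["excluded"].astype(bool)
    if f.urgency == "urgent_only":
        mask &= df["gap"] >= 0
    elif f.urgency == "easy_only":
        mask &= df["gap"] < 0
    rpt = df["rpt"] if "rpt" in df.columns else df["rt"] - df["gap"]
    if f.rpt_min is not None:
        mask &= rpt >= f.rpt_min
    if f.rpt_max is not None:
        mask &= rpt <= f.rpt_max
    if f.trial_types is not None:
        mask &= df["trial_type"].isin(f.trial_types)
    if f.experiments is not None:
        mask &= df["experiment"].isin(f.experiments)
    if f.participants is not None:
        mask &= df["participant"].isin(f.participants)
    out = df[mask]
    logger.debug("filter %s: %d -> %d trials", f, len(df), len(out))
    return out


def trials_from_records(records: Iterable[Trial | Mapping]) -> pd.DataFrame:
    """Build a canonical table from Trial objects or dicts (testing helper)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
        rows.append(d)
    df = pd.DataFrame(rows)
    for col, default in (("excluded", False), ("exclusion_reason", "none")):
        if col not in df.columns:
            df[col] = default
    df = df.astype({k: v for k, v in _DTYPES.items() if k in df.columns})
    df["rpt"] = df["rt"] - df["gap"]
    return df[list(CANONICAL_COLUMNS) + ["rpt"]]
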