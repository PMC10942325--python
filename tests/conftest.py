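import numpy as np
import pandas as pd
import pytest

from tachy.io import trials_from_records


def make_trials(rows):
    """Build a canonical trial table from compact dicts.

    Each dict needs at least gap, rt (or rpt with gap=0) and may override any
    canonical column; correctness defaults to consistency with the sides.
    """
    full = []
    for r in rows:
        d = {
            "participant": "p1",
            "experiment": 1,
            "trial_type": "pro",
            "cue_side": "right",
            "gap": 0.0,
            "excluded": False,
            "exclusion_reason": "none",
        }
        d.update(r)
        if "rt" not in d and "rpt" in d:
            d["rt"] = d.pop("rpt") + d["gap"]
        d.pop("rpt", None)
        if "choice_side" not in d and "correct" in d:
            same = (d["trial_type"] == "pro") == bool(d["correct"])
            other = "left" if d["cue_side"] == "right" else "right"
            d["choice_side"] = d["cue_side"] if same else other
        if "correct" not in d:
            same = d.get("choice_side", d["cue_side"]) == d["cue_side"]
            d["correct"] = same if d["trial_type"] == "pro" else not same
        d.setdefault("choice_side", d["cue_side"])
        full.append(d)
    return trials_from_records(full)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bernoulli_trials():
    """Trials with rpt uniform on [0, 300] and a known accuracy function."""

    def _make(p_fn, n, seed=0):
        r = np.random.default_rng(seed)
        rpt = r.uniform(0, 300, n)
        correct = r.random(n) < p_fn(rpt)
        return make_trials(
            [{"gap": 0.0, "rt": float(t), "correct": bool(c)}
             for t, c in zip(rpt, correct)]
        )

    return _make
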