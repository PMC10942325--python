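import numpy as np
import pytest

from tachy.io import AnalysisConfig
from tachy.metrics import (
    CAPTURE_WINDOW,
    ParticipantBiasCost,
    antisaccade_cost,
    bias_cost_differences,
    capture_fraction,
    derive_capture_window,
    guess_bias,
    range_summary,
    reliable_performers,
)
from tachy.sigmoid import SigmoidFit, sigmoid_eval
from tachy.tachometric import TachometricCurve

from conftest import make_trials


def curve_from_values(centers, frac):
    frac = np.asarray(frac, dtype=float)
    n = np.full(centers.size, 100)
    return TachometricCurve(
        centers=np.asarray(centers, dtype=float), n_total=n,
        n_correct=np.round(frac * 100), frac_correct=frac,
        ci_low=frac, ci_high=frac, bin_width=31.0,
    )


class TestDeriveCaptureWindow:
    def test_mirrored_pair_crossing_at_80_and_126(self):
        centers = np.arange(0.0, 301.0, 1.0)
        bump = np.where((centers > 80) & (centers < 126),
                        0.2 * np.sin(np.pi * (centers - 80) / 46), 0.0)
        pro = curve_from_values(centers, 0.5 + bump)
        anti = curve_from_values(centers, 0.5 - bump)  # exact mirror
        window = derive_capture_window((pro, anti))
        assert window == (81.0, 125.0)  # all bins strictly inside (80, 126)

    def test_flat_curves_give_none(self):
        centers = np.arange(0.0, 301.0, 1.0)
        flat = curve_from_values(centers, np.full(centers.size, 0.5))
        assert derive_capture_window((flat, flat)) is None

    def test_intersection_across_pairs(self):
        centers = np.arange(0.0, 301.0, 1.0)

        def pair(lo, hi):
            bump = np.where((centers > lo) & (centers < hi), 0.15, 0.0)
            return (curve_from_values(centers, 0.5 + bump),
                    curve_from_values(centers, 0.5 - bump))

        window = derive_capture_window([pair(80, 130), pair(90, 140)])
        assert window == (91.0, 129.0)

    def test_mismatched_grids_rejected(self):
        a = curve_from_values(np.arange(0.0, 301.0), np.full(301, 0.6))
        b = curve_from_values(np.arange(0.0, 201.0), np.full(201, 0.4))
        with pytest.raises(ValueError):
            derive_capture_window((a, b))


class TestCaptureFraction:
    def test_default_window_is_83_124(self):
        assert CAPTURE_WINDOW == (83.0, 124.0)
        assert AnalysisConfig().capture_window == (83.0, 124.0)

    def test_saturated_capture(self):
        trials = make_trials(
            [{"trial_type": "pro", "gap": 0, "rt": 100.0, "correct": True}] * 5
            + [{"trial_type": "anti", "gap": 0, "rt": 100.0, "correct": False}] * 5
        )
        res = capture_fraction(trials)
        assert res.frac_correct_pro == 1.0
        assert res.frac_correct_anti == 0.0

    def test_hand_tallied_fixture(self):
        # 8 trials inside [83, 124] (boundary values included), 2 outside
        rows = [
            ("pro", 83.0, True), ("pro", 124.0, False), ("pro", 100.0, True),
            ("pro", 82.9, True),   # outside
            ("anti", 90.0, False), ("anti", 110.0, False), ("anti", 120.0, True),
            ("anti", 124.0, False), ("anti", 83.0, True),
            ("anti", 124.1, True),  # outside
        ]
        trials = make_trials(
            [{"trial_type": tt, "gap": 0, "rt": r, "correct": c} for tt, r, c in rows]
        )
        res = capture_fraction(trials)
        assert (res.n_pro, res.n_anti) == (3, 5)
        assert res.frac_correct_pro == pytest.approx(2 / 3)
        assert res.frac_correct_anti == pytest.approx(2 / 5)

    def test_ci_brackets_fraction(self):
        trials = make_trials(
            [{"trial_type": "pro", "gap": 0, "rt": 100.0, "correct": i % 3 > 0}
             for i in range(30)]
        )
        res = capture_fraction(trials)
        assert res.ci_pro[0] <= res.frac_correct_pro <= res.ci_pro[1]


class TestGuessBias:
    def test_symmetric_counts_give_half(self):
        trials = make_trials(
            [{"gap": 0, "rt": 50.0, "cue_side": "right",
              "choice_side": "right" if i % 2 else "left"} for i in range(10)]
        )
        assert guess_bias(trials).frac_toward_cue == 0.5

    def test_anti_errors_count_toward_cue(self):
        # hand tally: toward-cue = pro-correct (2) + anti-incorrect (2) = 4 of 6
        rows = [
            {"trial_type": "pro", "correct": True},    # toward
            {"trial_type": "pro", "correct": True},    # toward
            {"trial_type": "pro", "correct": False},   # away
            {"trial_type": "anti", "correct": False},  # toward (chose cue side)
            {"trial_type": "anti", "correct": False},  # toward
            {"trial_type": "anti", "correct": True},   # away
        ]
        trials = make_trials([dict(r, gap=0, rt=60.0) for r in rows])
        gb = guess_bias(trials)
        assert (gb.n_toward_cue, gb.n_toward_noncue) == (4, 2)
        assert gb.frac_toward_cue == pytest.approx(4 / 6)

    def test_bound_is_inclusive_at_75(self):
        trials = make_trials(
            [{"gap": 0, "rt": 75.0, "correct": True},
             {"gap": 0, "rt": 75.1, "correct": True}]
        )
        gb = guess_bias(trials)
        assert gb.n_toward_cue + gb.n_toward_noncue == 1

    def test_pooled_scale_counts(self):
        # fraction implied by counts 9015 toward / 7154 away
        assert 9015 / (9015 + 7154) == pytest.approx(0.5575, abs=5e-4)


class TestAntisaccadeCost:
    def test_identical_fits_zero_cost(self):
        fit = SigmoidFit(A=0.9, B=0.5, C=165.0, D=20.0, mae=0.0)
        res = antisaccade_cost(fit, fit)
        assert res.delta_rpt == pytest.approx(0.0)
        assert res.delta_bias == pytest.approx(0.0)

    def test_worked_example_with_baseline_shift(self):
        pro = SigmoidFit(A=0.95, B=0.60, C=165.0, D=20.0, mae=0.0)
        anti = SigmoidFit(A=0.95, B=0.40, C=195.0, D=20.0, mae=0.0)
        res = antisaccade_cost(pro, anti)
        assert res.criterion_level == pytest.approx(0.775)
        assert res.delta_bias == pytest.approx(0.20)
        # closed-form logistic inverse oracle for both curves
        z = (0.775 - 0.40) / (0.95 - 0.40)
        rpt_anti = 195.0 + 20.0 * np.log(z / (1 - z))
        expected = rpt_anti - 165.0  # pro attains its own halfway at C
        assert res.delta_rpt == pytest.approx(expected)
        assert res.delta_rpt == pytest.approx(45.2, abs=0.1)
        # numeric cross-check: both fitted curves hit the criterion there
        assert sigmoid_eval(165.0, pro.params) == pytest.approx(0.775)
        assert sigmoid_eval(rpt_anti, anti.params) == pytest.approx(0.775)

    def test_unattainable_criterion_is_undefined(self):
        pro = SigmoidFit(A=0.96, B=0.60, C=165.0, D=20.0, mae=0.0)  # halfway 0.78
        anti = SigmoidFit(A=0.60, B=0.40, C=195.0, D=20.0, mae=0.0)
        res = antisaccade_cost(pro, anti)
        assert res.delta_rpt is None


class TestRangeSummary:
    def test_single_rpt_populates_transition_only(self):
        trials = make_trials([{"gap": 0, "rt": 150.0, "correct": True}] * 3)
        summary = range_summary(trials)
        counts = summary.set_index("range")["n"]
        assert counts["T"] == 3
        assert counts[["G", "C", "A"]].sum() == 0

    def test_rpt_80_belongs_to_no_range(self):
        trials = make_trials([{"gap": 0, "rt": 80.0, "correct": True}])
        summary = range_summary(trials)
        assert summary["n"].sum() == 0

    def test_twelve_trial_fixture_hand_tally(self):
        rows = [
            (50.0, True), (75.0, False), (60.0, True),            # G: 3, 2 correct
            (83.0, True), (124.0, True), (100.0, False),          # C: 3, 2 correct
            (135.0, True), (199.9, False),                        # T: 2, 1 correct
            (200.0, True), (250.0, True), (300.0, False), (400.0, True),  # A: 4, 3
        ]
        trials = make_trials([{"gap": 0, "rt": r, "correct": c} for r, c in rows])
        summary = range_summary(trials).set_index("range")
        assert summary.loc["G", "n"] == 3 and summary.loc["G", "n_correct"] == 2
        assert summary.loc["C", "n"] == 3 and summary.loc["C", "n_correct"] == 2
        assert summary.loc["T", "n"] == 2 and summary.loc["T", "n_correct"] == 1
        assert summary.loc["A", "n"] == 4 and summary.loc["A", "n_correct"] == 3

    def test_transition_upper_bound_exclusive(self):
        trials = make_trials(
            [{"gap": 0, "rt": 200.0, "correct": True},
             {"gap": 0, "rt": 199.999, "correct": True}]
        )
        summary = range_summary(trials).set_index("range")
        assert summary.loc["T", "n"] == 1
        assert summary.loc["A", "n"] == 1

    def test_bias_cost_differences_columns(self):
        rows = []
        for tt, frac in (("pro", 0.8), ("anti", 0.5)):
            for i in range(20):
                rows.append({"trial_type": tt, "gap": 0, "rt": 150.0,
                             "correct": i < frac * 20})
                rows.append({"trial_type": tt, "gap": 0, "rt": 50.0,
                             "correct": i < frac * 20})
        diffs = bias_cost_differences(range_summary(make_trials(rows)))
        assert diffs.loc[0, "diff_T"] == pytest.approx(0.3)
        assert diffs.loc[0, "diff_G"] == pytest.approx(0.3)


class TestReliablePerformers:
    @staticmethod
    def _easy_block(pid, experiment, tt, frac, n=20):
        return [
            {"participant": pid, "experiment": experiment, "trial_type": tt,
             "gap": -100, "rt": 150.0, "correct": i < round(frac * n)}
            for i in range(n)
        ]

    def test_strict_inequality_on_all_eight_cells(self):
        rows = []
        for exp in (1, 2, 3, 4):
            for tt in ("pro", "anti"):
                rows += self._easy_block("good", exp, tt, 0.9)
                # "edge" sits exactly at 0.7 in one cell: strict > fails
                frac = 0.7 if (exp, tt) == (1, "pro") else 0.9
                rows += self._easy_block("edge", exp, tt, frac)
                rows += self._easy_block("bad", exp, tt, 0.5)
        trials = make_trials(rows)
        assert reliable_performers(trials) == ["good"]

    def test_missing_cell_disqualifies(self):
        rows = []
        for exp in (1, 2, 3, 4):
            for tt in ("pro", "anti"):
                if (exp, tt) != (4, "anti"):
                    rows += self._easy_block("partial", exp, tt, 0.9)
                rows += self._easy_block("full", exp, tt, 0.9)
        assert reliable_performers(make_trials(rows)) == ["full"]

    def test_no_easy_trials(self):
        trials = make_trials([{"gap": 0, "rt": 100.0}])
        assert reliable_performers(trials) == []
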