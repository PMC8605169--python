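"""SQC strategy selection and the Westgard multirule engine."""

import pytest

from usigma import (
    ComputationError,
    QCRunSeries,
    SQCStrategy,
    UnknownRuleError,
    ValidationError,
    evaluate_rules,
    schedule_qc,
    select_strategy,
)
from usigma.datasets import ANALYTES, LABS, SURVEY_SIGMA, SURVEY_STRATEGY

# ----------------------------------------------------------------- selection


class TestSelectStrategy:
    @pytest.mark.parametrize(
        "sigmas,rules,n,run",
        [
            ({"level1": 5.94, "level2": 5.97}, ("1_3s", "2_2s", "R_4s"), 2, 450),
            ({"level1": 7.14, "level2": 7.46}, ("1_3s",), 2, 1000),
            ({"level1": 4.77, "level2": 4.98}, ("1_3s", "2_2s", "R_4s", "4_1s"), 4, 200),
        ],
    )
    def test_survey_anchors(self, sigmas, rules, n, run):
        s = select_strategy(sigmas)
        assert (s.rules, s.n_controls, s.run_size) == (rules, n, run)

    def test_min_policy_uses_worst_level(self):
        s = select_strategy({"level1": 6.5, "level2": 5.2})
        assert s.run_size == 450

    def test_low_sigma_bands(self):
        s3 = select_strategy({"level1": 3.4})
        assert s3.rules == ("1_3s", "2_2s", "R_4s", "4_1s", "8_x")
        assert (s3.n_controls, s3.run_size, s3.improvement_required) == (4, 45, False)
        s2 = select_strategy({"level1": 2.1})
        assert (s2.run_size, s2.events, s2.improvement_required) == (23, 2, True)

    def test_full_survey_reproduction(self):
        # all 50 (lab, analyte) sigma pairs map onto the survey's strategy cells
        for analyte in ANALYTES:
            for lab in LABS:
                s1, s2 = SURVEY_SIGMA[analyte][lab]
                s = select_strategy({"level1": s1, "level2": s2}, policy="min")
                assert (s.rules, s.n_controls, s.run_size) == SURVEY_STRATEGY[analyte][lab], (
                    analyte, lab)

    def test_monotone_stringency(self):
        # decreasing sigma never shrinks the rule set, never lengthens the run
        sigmas = [8.0, 6.0, 5.5, 5.0, 4.5, 4.0, 3.5, 3.0, 2.5, 1.0]
        prev = select_strategy({"l": sigmas[0]})
        for s in sigmas[1:]:
            cur = select_strategy({"l": s})
            assert set(prev.rules) <= set(cur.rules)
            assert cur.run_size <= prev.run_size
            prev = cur

    def test_empty_map_rejected(self):
        with pytest.raises(ComputationError):
            select_strategy({})

    def test_strategy_validation(self):
        with pytest.raises(UnknownRuleError, match="2_3s"):
            SQCStrategy(("1_3s", "2_3s"), 2, 450, band="6>sigma>=5")
        with pytest.raises(ValidationError):
            SQCStrategy(("1_3s",), 3, 450, band="6>sigma>=5")


# --------------------------------------------------------------- rule engine


def _series(z_by_run, sd=1.0):
    """Build a QCRunSeries whose z-scores equal the given per-run tuples."""
    obs = []
    for run, zs in enumerate(z_by_run, start=1):
        for i, z in enumerate(zs):
            level = f"level{i + 1}"
            obs.append((run, level, 10.0 + z * sd))
    levels = {f"level{i + 1}" for zs in z_by_run for i in range(len(zs))}
    return QCRunSeries(tuple(obs), means={lv: 10.0 for lv in levels},
                       sds={lv: sd for lv in levels})


def _strategy(*rules):
    return SQCStrategy(tuple(rules), 2, 450, band="6>sigma>=5")


class TestEvaluateRules:
    def test_1_3s_single_outlier(self):
        (ev,) = evaluate_rules(_series([(3.2, 0.1)]), _strategy("1_3s"))
        assert ev.decision == "reject" and ev.violated_rules == ("1_3s",)

    def test_2_2s_within_run(self):
        (ev,) = evaluate_rules(_series([(2.1, 2.3)]), _strategy("1_3s", "2_2s", "R_4s"))
        assert "2_2s" in ev.violated_rules

    def test_2_2s_across_runs(self):
        evs = evaluate_rules(_series([(0.1, 2.1), (2.3, 0.0)]),
                             _strategy("1_3s", "2_2s"))
        # the pair completes at run 2's first observation
        assert evs[0].decision == "accept"
        assert evs[1].violated_rules == ("2_2s",)

    def test_r_4s_depends_on_selected_rules(self):
        runs = [(2.1, -2.2)]
        (ev,) = evaluate_rules(_series(runs), _strategy("1_3s", "2_2s", "R_4s"))
        assert ev.violated_rules == ("R_4s",)
        (ev,) = evaluate_rules(_series(runs), _strategy("1_3s"))
        assert ev.decision == "accept"

    def test_r_4s_is_within_run_only(self):
        evs = evaluate_rules(_series([(2.1, 0.0), (0.0, -2.2)]),
                             _strategy("R_4s"))
        assert all(ev.decision == "accept" for ev in evs)

    def test_4_1s_four_consecutive(self):
        evs = evaluate_rules(_series([(1.2, 1.4), (1.1, 1.3)]),
                             _strategy("1_3s", "2_2s", "R_4s", "4_1s"))
        assert "4_1s" in evs[1].violated_rules

    def test_8_x_same_side_of_mean(self):
        runs = [(0.3, 0.5)] * 4  # eight consecutive positives
        evs = evaluate_rules(_series(runs), _strategy("1_3s", "8_x"))
        assert evs[3].violated_rules == ("8_x",)
        assert all(ev.decision == "accept" for ev in evs[:3])

    def test_in_control_data_all_accepted(self):
        runs = [(0.4, -0.6), (1.1, 0.2), (-1.5, 0.9), (0.0, -0.3)]
        evs = evaluate_rules(_series(runs),
                             _strategy("1_3s", "2_2s", "R_4s", "4_1s", "8_x"))
        assert [ev.decision for ev in evs] == ["accept"] * 4

    def test_series_validation(self):
        with pytest.raises(ValidationError):
            QCRunSeries(((1, "level1", 10.0),), means={"level1": 10.0},
                        sds={"level1": 0.0})
        with pytest.raises(ValidationError):
            QCRunSeries(((1, "level9", 10.0),), means={"level1": 10.0},
                        sds={"level1": 1.0})


class TestScheduleQC:
    @pytest.mark.parametrize(
        "run_size,daily,events", [(450, 900, 2), (1000, 100, 1), (200, 201, 2)]
    )
    def test_ceiling(self, run_size, daily, events):
        assert schedule_qc(run_size, daily) == events

    def test_positive_inputs_required(self):
        with pytest.raises(ValidationError):
            schedule_qc(0, 100)
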