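"""CV, bias, sigma, DPM, QGI and the improvement classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from usigma import (
    ComputationError,
    InsufficientDataError,
    PerformanceRecord,
    ScenarioConfig,
    classify_improvement,
    compute_bias,
    compute_cv,
    qgi,
    sigma_metric,
    sigma_to_dpm,
    simulate_iqc,
)
from usigma.datasets import SURVEY_QGI, SURVEY_TEA

# ------------------------------------------------------------------------ CV


class TestComputeCV:
    def test_zero_variance_flagged(self, make_series):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert compute_cv(make_series([10, 10, 10])) == 0.0

    def test_hand_value(self, make_series):
        # SD([9,10,11]) = 1 with n-1 denominator, mean 10 -> CV 10%
        assert compute_cv(make_series([9, 10, 11])) == pytest.approx(10.0)

    def test_sampling_error_within_chi_square_band(self):
        # n=360 draws at true CV 4%: the 99% chi-square interval for the SD
        # is 4 * sqrt(chi2_q(n-1)/(n-1)), well inside [3.6, 4.4]
        cfg = ScenarioConfig("L", "K", "level1", 25.0, 4.0, 0.0, n_iqc_values=360, seed=1)
        est = compute_cv(simulate_iqc(cfg))
        lo, hi = (4.0 * math.sqrt(chi2.ppf(q, 359) / 359) for q in (0.005, 0.995))
        assert lo <= est <= hi
        assert 3.6 <= est <= 4.4

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            compute_cv(np.array([10.0]))
        with pytest.raises(ComputationError):
            compute_cv(np.array([-1.0, 1.0]))  # mean 0


# ---------------------------------------------------------------------- bias


class TestComputeBias:
    def test_replicates_equal_target(self, make_eqa):
        assert compute_bias(make_eqa([10.0] * 5, target=10.0)).bias_percent == 0.0

    def test_hand_value(self, make_eqa):
        res = compute_bias(make_eqa([10.2, 10.1, 10.3, 10.2, 10.2], target=10.0))
        assert res.bias_percent == pytest.approx(2.0)
        assert res.per_replicate_bias_percent == pytest.approx((2.0, 1.0, 3.0, 2.0, 2.0))

    def test_convention_gap_on_alternating_offsets(self, make_eqa):
        # offsets +2%, -2%, +2%, -2%, +2%: signed mean 0.4, absolute mean 2.0
        eqa = make_eqa([10.2, 9.8, 10.2, 9.8, 10.2], target=10.0)
        assert compute_bias(eqa, "mean_then_abs").bias_percent == pytest.approx(0.4)
        assert compute_bias(eqa, "abs_then_mean").bias_percent == pytest.approx(2.0)

    def test_unknown_convention(self, make_eqa):
        with pytest.raises(ValueError):
            compute_bias(make_eqa([10.0] * 5, target=10.0), "median")


# --------------------------------------------------------------------- sigma


class TestSigmaMetric:
    def test_constructed_identity(self):
        assert sigma_metric(20.0, 0.0, 20.0 / 6.0) == pytest.approx(6.0)

    def test_survey_reconstruction(self):
        # inputs recovered by solving sigma=5.69 and QGI=0.23 against TEa=21:
        # cv = tea/(sigma + 1.5*qgi), bias = 1.5*qgi*cv -> (3.48, 1.20)
        cv = 21.0 / (5.69 + 1.5 * 0.23)
        bias = 1.5 * 0.23 * cv
        assert cv == pytest.approx(3.48, abs=0.005)
        assert bias == pytest.approx(1.20, abs=0.005)
        assert sigma_metric(21.0, bias, cv) == pytest.approx(5.69, abs=0.01)

    def test_bias_beyond_goal_is_negative(self):
        assert sigma_metric(20.0, 25.0, 5.0) == pytest.approx(-1.0)

    def test_zero_cv_is_infinite_sentinel(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert sigma_metric(20.0, 1.0, 0.0) == math.inf


class TestSigmaToDPM:
    def test_world_class_anchor(self):
        assert round(sigma_to_dpm(6.0), 1) == 3.4

    def test_tail_at_zero(self):
        assert sigma_to_dpm(1.5) == pytest.approx(500000.0)

    def test_normal_tail_oracle(self):
        # erf oracle: 1e6 * Phi_bar(3) = 1349.9
        assert sigma_to_dpm(4.5) == pytest.approx(1350.0, abs=1.0)

    def test_monotone_decreasing(self):
        grid = np.linspace(-2, 8, 41)
        dpm = [sigma_to_dpm(s) for s in grid]
        assert all(a > b for a, b in zip(dpm, dpm[1:]))


# ----------------------------------------------------------- QGI and classes


class TestQGI:
    @pytest.mark.parametrize(
        "bias,cv,expected", [(0.0, 5.0, 0.0), (3.0, 2.0, 1.0)]
    )
    def test_exact_ratios(self, bias, cv, expected):
        assert qgi(bias, cv) == pytest.approx(expected)

    def test_survey_reconstruction(self):
        cv = 21.0 / (5.69 + 1.5 * 0.23)
        assert qgi(1.5 * 0.23 * cv, cv) == pytest.approx(0.23, abs=0.005)

    def test_zero_cv_rejected(self):
        with pytest.raises(ComputationError):
            qgi(1.0, 0.0)


class TestClassifyImprovement:
    @pytest.mark.parametrize(
        "sigma,q,expected",
        [
            (5.69, 0.23, "imprecision"),
            (5.66, 1.27, "trueness"),
            (5.94, 0.85, "both"),
            (5.0, 0.8, "both"),   # boundary equality belongs to the middle class
            (5.0, 1.2, "both"),
            (6.0, None, "none"),
            (7.5, 3.0, "none"),
        ],
    )
    def test_classes(self, sigma, q, expected):
        assert classify_improvement(sigma, q) == expected

    def test_qgi_required_below_six(self):
        with pytest.raises(ComputationError):
            classify_improvement(5.0, None)

    def test_exhaustive_and_exclusive_over_qgi_axis(self):
        classes = {classify_improvement(5.0, q) for q in np.linspace(0, 10, 2001)}
        assert classes == {"imprecision", "both", "trueness"}


# ------------------------------------------------------------ property tests

finite_pct = st.floats(0.5, 50.0, allow_nan=False)


class TestInvariants:
    @settings(derandomize=True, max_examples=200)
    @given(
        scale=st.floats(1e-3, 1e3),
        mean=st.floats(1.0, 1000.0),
        cv=st.floats(0.5, 10.0),
        bias=st.floats(-10.0, 10.0),
    )
    def test_scale_invariance(self, scale, mean, cv, bias):
        # multiplying every concentration by c > 0 changes no percent-based metric
        from usigma import EQAReplicateSet, IQCSeries

        base = np.array([mean * (1 + 0.01 * cv * z) for z in (-1.2, -0.4, 0.3, 1.3)])
        eqa_vals = tuple([mean * (1 + bias / 100.0)] * 5)
        cv1 = compute_cv(IQCSeries("L", "K", "level1", tuple(base)))
        cv2 = compute_cv(IQCSeries("L", "K", "level1", tuple(base * scale)))
        b1 = compute_bias(
            EQAReplicateSet("L", "K", "level1", eqa_vals, mean)
        ).bias_percent
        b2 = compute_bias(
            EQAReplicateSet("L", "K", "level1",
                            tuple(v * scale for v in eqa_vals), mean * scale)
        ).bias_percent
        assert cv1 == pytest.approx(cv2, rel=1e-9)
        assert b1 == pytest.approx(b2, rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(tea=finite_pct, bias=st.floats(0.0, 20.0), cv=st.floats(0.1, 20.0))
    def test_consistency_identity(self, tea, bias, cv):
        # qgi*1.5*cv + sigma*cv = |bias| + (tea - |bias|) = tea
        s = sigma_metric(tea, bias, cv)
        assert qgi(bias, cv) * 1.5 * cv + s * cv == pytest.approx(tea, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(tea=finite_pct, bias=st.floats(0.0, 20.0), cv=st.floats(0.1, 20.0),
           delta=st.floats(0.01, 5.0))
    def test_sigma_strictly_decreasing_in_bias_and_cv(self, tea, bias, cv, delta):
        s = sigma_metric(tea, bias, cv)
        assert sigma_metric(tea, bias + delta, cv) < s
        if tea > bias:  # positive numerator: larger CV dilutes the margin
            assert sigma_metric(tea, bias, cv + delta) < s


class TestSurveyRoundTrip:
    """Printed (sigma, QGI, TEa) triples pin down (CV, bias); pushing the
    reconstruction back through the metrics must reproduce the prints."""

    @pytest.mark.parametrize("row", SURVEY_QGI, ids=lambda r: f"{r[0]}-{r[1]}")
    @pytest.mark.parametrize("level_idx", [0, 1], ids=["level1", "level2"])
    def test_round_trip_two_decimals(self, row, level_idx):
        analyte, lab, s1, s2, q1, q2, _ = row
        s, q = (s1, q1) if level_idx == 0 else (s2, q2)
        tea = SURVEY_TEA[analyte]
        cv = tea / (s + 1.5 * q)
        bias = 1.5 * q * cv
        assert round(sigma_metric(tea, bias, cv), 2) == s
        assert round(qgi(bias, cv), 2) == q


class TestPerformanceRecord:
    def test_derived_fields(self):
        r = PerformanceRecord("A", "Urea", "level1", cv_percent=3.48,
                              bias_percent=1.20, tea_percent=21.0)
        assert r.sigma == pytest.approx((21.0 - 1.20) / 3.48)
        assert r.qgi == pytest.approx(1.20 / (1.5 * 3.48))
        assert r.zone == "6>sigma>=5"
        assert r.improvement == "imprecision"
        assert r.dpm > sigma_to_dpm(6.0)

    def test_qgi_absent_at_goal(self):
        r = PerformanceRecord("A", "Na", "level1", cv_percent=2.0,
                              bias_percent=1.0, tea_percent=26.0)
        assert r.sigma >= 6 and r.qgi is None and r.improvement == "none"

    def test_preconditions(self):
        with pytest.raises(ComputationError):
            PerformanceRecord("A", "K", "level1", cv_percent=0.0,
                              bias_percent=1.0, tea_percent=29.0)
        with pytest.raises(ComputationError):
            PerformanceRecord("A", "K", "level1", cv_percent=2.0,
                              bias_percent=-1.0, tea_percent=29.0)
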