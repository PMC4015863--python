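"""Effect-measure conversions: scale transforms, SE/CI/P algebra, 2x2 tables."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from trialsig.effects import (
    AnalysisScaleValue,
    Direction,
    EffectEstimate,
    Measure,
    Scale,
    TwoByTwoTable,
    ci_from_se,
    effects_from_table,
    p_from_estimate,
    rr_to_or,
    se_from_ci,
    se_from_p,
    to_analysis_scale,
)

fast = settings(max_examples=150, derandomize=True, database=None)


def est(measure, point, **kw):
    return EffectEstimate(measure=measure, point=point, **kw)


class TestAnalysisScale:
    @pytest.mark.parametrize(
        "measure,point,expected",
        [
            (Measure.OR, 0.92, math.log(0.92)),  # prints as -0.08
            (Measure.OR, 1.0, 0.0),
            (Measure.OR, 1.35, math.log(1.35)),  # prints as 0.30
            (Measure.HR, 0.92, math.log(0.92)),
            (Measure.MD, -2.5, -2.5),
        ],
    )
    def test_log_for_ratios_identity_for_md(self, measure, point, expected):
        v = to_analysis_scale(est(measure, point, p_two_sided=0.04))
        assert v.value == pytest.approx(expected, rel=1e-12)
        assert v.scale is (Scale.IDENTITY if measure is Measure.MD else Scale.LOG)

    def test_printed_roundings_of_worked_examples(self):
        assert round(math.log(0.92), 2) == -0.08
        assert round(math.log(1.35), 2) == 0.30

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            est(Measure.OR, -0.5, p_two_sided=0.04)


class TestSEFromCI:
    def test_published_hazard_ratio_ci(self):
        # HR 0.92 (0.86, 0.998): SE of the log ratio prints as 0.04
        se = se_from_ci(0.86, 0.998, 0.95, Scale.LOG)
        assert se == pytest.approx(0.037965, abs=1e-5)
        assert round(se, 2) == 0.04

    def test_unit_se_construction(self):
        z = 1.959963984540054
        assert se_from_ci(math.exp(-z), math.exp(z), 0.95, Scale.LOG) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_ci_narrower_than_count_based_se(self):
        # the (1.01, 1.36) interval implies a smaller SE than the 2x2 table's 0.142
        assert se_from_ci(1.01, 1.36, 0.95, Scale.LOG) == pytest.approx(0.0759, abs=2e-4)

    def test_crossed_bounds_rejected(self):
        with pytest.raises(ValueError):
            se_from_ci(1.2, 0.8)
        with pytest.raises(ValueError):
            se_from_ci(-0.1, 0.5, 0.95, Scale.LOG)

    @given(
        theta=st.floats(-3, 3),
        se=st.floats(0.01, 5),
        level=st.floats(0.5, 0.999),
    )
    @fast
    def test_round_trip_with_ci_from_se(self, theta, se, level):
        v = AnalysisScaleValue(theta, Scale.LOG, Measure.OR)
        lo, hi = ci_from_se(v, se, level)
        assert se_from_ci(lo, hi, level, Scale.LOG) == pytest.approx(se, rel=1e-10)


class TestWaldP:
    def test_null_estimate_gives_p_one(self):
        assert p_from_estimate(AnalysisScaleValue(0.0, Scale.LOG, Measure.OR), 0.3) == 1.0

    def test_three_sigma(self):
        p = p_from_estimate(AnalysisScaleValue(-0.12, Scale.LOG, Measure.OR), 0.04)
        assert p == pytest.approx(0.0026998, rel=1e-4)

    def test_threshold_definition(self):
        se = 0.7
        v = AnalysisScaleValue(1.959963984540054 * se, Scale.LOG, Measure.OR)
        assert p_from_estimate(v, se) == pytest.approx(0.05, rel=1e-9)

    def test_se_implied_by_example_p(self):
        v = AnalysisScaleValue(-0.0834, Scale.LOG, Measure.OR)
        assert se_from_p(v, 0.04) == pytest.approx(0.0834 / 2.0537489, rel=1e-6)

    @given(theta=st.floats(0.01, 2), se=st.floats(0.06, 5))
    @fast
    def test_p_and_se_are_mutual_inverses(self, theta, se):
        v = AnalysisScaleValue(theta, Scale.LOG, Measure.OR)
        p = p_from_estimate(v, se)
        assert 0 < p <= 1
        if p < 1:
            assert se_from_p(v, p) == pytest.approx(se, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        v = AnalysisScaleValue(0.5, Scale.LOG, Measure.OR)
        with pytest.raises(ValueError):
            p_from_estimate(v, 0.0)
        with pytest.raises(ValueError):
            se_from_p(v, 1.0)
        with pytest.raises(ValueError):
            se_from_p(AnalysisScaleValue(0.0, Scale.LOG, Measure.OR), 0.5)

    @given(
        theta=st.floats(-2, 2),
        se=st.floats(0.01, 2),
        level=st.floats(0.5, 0.99),
    )
    @fast
    def test_ci_excludes_null_iff_p_below_complement(self, theta, se, level):
        v = AnalysisScaleValue(theta, Scale.IDENTITY, Measure.MD)
        lo, hi = ci_from_se(v, se, level)
        excludes = lo > 0 or hi < 0
        assert excludes == (p_from_estimate(v, se) < (1 - level))


class TestTwoByTwo:
    def test_severe_sepsis_trial_counts(self):
        # 202/396 vs 173/402 events: the published log-OR SE is 0.142
        eff = effects_from_table(TwoByTwoTable(202, 194, 173, 229))
        assert eff.se_log_or == pytest.approx(0.14231, abs=1e-4)
        assert round(eff.se_log_or, 3) == 0.142
        assert eff.odds_ratio == pytest.approx(1.378, abs=1e-3)
        assert eff.risk_experimental == pytest.approx(202 / 396)
        assert eff.risk_control == pytest.approx(173 / 402)

    def test_symmetric_table(self):
        eff = effects_from_table(TwoByTwoTable(10, 10, 10, 10))
        assert eff.odds_ratio == 1.0
        assert eff.risk_difference == 0.0

    def test_zero_cell_continuity_correction(self):
        eff = effects_from_table(TwoByTwoTable(1, 0, 1, 1))
        assert eff.continuity_corrected
        for value in (eff.odds_ratio, eff.log_or, eff.se_log_or, eff.risk_ratio):
            assert math.isfinite(value)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(0, 0, 5, 5)

    @pytest.mark.parametrize("p0,rr", [(0.5, 0.8), (0.2, 0.9), (0.25, 1.2), (0.5, 1.0)])
    def test_or_matches_exact_table_at_one_million(self, p0, rr):
        # the implied-OR conversion equals the OR of the exact 2x2 table
        n = 1_000_000
        p1 = rr * p0
        t = TwoByTwoTable(round(p1 * n), round((1 - p1) * n), round(p0 * n), round((1 - p0) * n))
        assert effects_from_table(t).odds_ratio == pytest.approx(rr_to_or(rr, p0), rel=1e-9)


class TestRRtoOR:
    @pytest.mark.parametrize(
        "rr,p0,expected",
        [
            (0.90, 0.20, 0.87805),  # the published chain prints 0.89
            (1.0, 0.3, 1.0),
            (0.80, 0.50, 2 / 3),  # matches the published odds ratio of 0.67
        ],
    )
    def test_known_conversions(self, rr, p0, expected):
        assert rr_to_or(rr, p0) == pytest.approx(expected, rel=1e-4)

    def test_impossible_risk_rejected(self):
        with pytest.raises(ValueError):
            rr_to_or(2.5, 0.5)


class TestEffectEstimateResolution:
    def test_se_precedence_ci_over_p(self):
        e = est(
            Measure.HR, 0.92, ci_lower=0.86, ci_upper=0.998, p_two_sided=0.04,
            direction_of_benefit=Direction.LESS_THAN_NULL,
        )
        theta, se, p = e.resolve()
        assert e.se_source == "ci"
        assert theta.value == pytest.approx(math.log(0.92))
        assert se == pytest.approx(0.037965, abs=1e-5)
        assert p == 0.04  # the supplied exact P is reported unchanged

    def test_warns_when_ci_and_p_disagree(self):
        e = est(Measure.OR, 0.5, ci_lower=0.4, ci_upper=0.62, p_two_sided=0.5)
        with pytest.warns(UserWarning, match="disagree"):
            e.resolve()

    def test_p_only_resolution(self):
        e = est(Measure.OR, 0.89, p_two_sided=0.0035)
        theta, se, p = e.resolve()
        assert e.se_source == "p"
        assert round(se, 2) == 0.04

    def test_needs_some_uncertainty_input(self):
        with pytest.raises(ValueError):
            est(Measure.OR, 0.9)
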