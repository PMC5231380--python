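"""Projection shapes, back-solving, and counterfactual construction."""

import math
import warnings

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from warhealth.core import Flag, Indicator, IndicatorSeries, Shape, StudyConfig, UnitMeta, round_half_up
from warhealth.counterfactual import (
    NegativeProjectionWarning,
    ProjectionError,
    back_solve_rate,
    build_counterfactual,
    project,
    sensitivity_analysis,
)

SHAPES = list(Shape)
rates = st.floats(-0.5, 0.5)
baselines = st.floats(0.01, 1e3)
horizons = st.integers(0, 40)


class TestProject:
    def test_compound_reproduces_national_mmr_counterfactual(self):
        value = project(0.60, -0.08, 20, Shape.COMPOUND)
        assert value == pytest.approx(0.1132, abs=5e-5)
        assert round_half_up(value, 2) == 0.11

    def test_compound_vs_linear_at_printed_national_rate(self):
        # the published counterfactual (15.04) is only approachable by
        # compounding; arithmetic-linear projection lands at 6.8
        assert project(34, -0.04, 20, Shape.COMPOUND) == pytest.approx(15.03, abs=5e-3)
        assert project(34, -0.04, 20, Shape.LINEAR) == pytest.approx(6.8)

    @given(baselines, st.sampled_from(SHAPES), horizons)
    def test_zero_rate_is_identity(self, v0, shape, t):
        assert project(v0, 0.0, t, shape) == pytest.approx(v0)

    @given(baselines, rates, st.sampled_from(SHAPES))
    def test_projection_anchors_at_baseline(self, v0, rate, shape):
        assume(shape is not Shape.COMPOUND or rate > -1)
        assert project(v0, rate, 0, shape) == pytest.approx(v0)

    @given(baselines, st.floats(-0.3, -0.001), st.integers(1, 40))
    def test_compound_and_exponential_decrease_and_stay_positive(self, v0, rate, t):
        for shape in (Shape.COMPOUND, Shape.EXPONENTIAL):
            now = project(v0, rate, t, shape)
            prev = project(v0, rate, t - 1, shape)
            assert 0 < now < prev

    def test_linear_warns_exactly_when_projection_is_negative(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            project(34, -0.04, 20, Shape.LINEAR)  # 6.8, fine
            assert not caught
        with pytest.warns(NegativeProjectionWarning):
            assert project(34, -0.06, 20, Shape.LINEAR) < 0

    def test_compound_rejects_rate_at_or_below_minus_one(self):
        with pytest.raises(ProjectionError):
            project(10.0, -1.0, 5, Shape.COMPOUND)

    @given(baselines, st.floats(-0.01, 0.01), st.integers(1, 25))
    def test_compound_and_exponential_agree_to_first_order(self, v0, rate, t):
        gap = abs(
            project(v0, rate, t, Shape.COMPOUND)
            - project(v0, rate, t, Shape.EXPONENTIAL)
        )
        # relative gap is O(rate^2 * t); vanishing as rate -> 0
        assert gap / v0 <= 10 * t * rate**2 + 1e-12


class TestBackSolve:
    @pytest.mark.parametrize(
        "baseline, target, years, expected",
        [
            (34.0, 15.04, 20, -0.03996),
            (0.60, 0.11, 20, -0.0811),
        ],
    )
    def test_closed_form_values(self, baseline, target, years, expected):
        assert back_solve_rate(baseline, target, years, Shape.COMPOUND) == pytest.approx(
            expected, abs=5e-4
        )

    @given(baselines, st.integers(1, 40), st.sampled_from(SHAPES))
    def test_same_value_back_solves_to_zero(self, v0, t, shape):
        assert back_solve_rate(v0, v0, t, shape) == pytest.approx(0.0, abs=1e-12)

    @given(
        baselines,
        st.floats(-0.2, 0.2),
        st.integers(1, 40),
        st.sampled_from([Shape.COMPOUND, Shape.LINEAR, Shape.EXPONENTIAL]),
    )
    def test_back_solve_inverts_project(self, v0, rate, t, shape):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NegativeProjectionWarning)
            target = project(v0, rate, t, shape)
        assume(target > 1e-9)
        solved = back_solve_rate(v0, target, t, shape)
        assert solved == pytest.approx(rate, abs=1e-10)

    def test_non_positive_inputs_are_errors(self):
        with pytest.raises(ProjectionError):
            back_solve_rate(0.0, 1.0, 10)
        with pytest.raises(ProjectionError):
            back_solve_rate(1.0, -1.0, 10)


def _district_series(rate_pre=-0.058, baseline=16.0, actual_end=11.8):
    """Pre-war segment pinned to a chosen two-point rate, plus an endpoint."""
    start = baseline / (1 + rate_pre * 7)
    return IndicatorSeries(
        "Vavuniya", Indicator.IMR, {1975: start, 1982: baseline, 2002: actual_end}
    )


class TestBuildCounterfactual:
    def test_projected_endpoint_matches_printed_district_value(self):
        # baseline 16, pre-war rate -0.058 compounded 20 years -> 4.84 (4.8)
        cf = build_counterfactual(
            _district_series(), UnitMeta("Vavuniya", "HIGH"), StudyConfig()
        )
        assert cf.rate == pytest.approx(-0.058, abs=1e-12)
        assert cf.endpoint_value == pytest.approx(4.843, abs=2e-3)
        assert round_half_up(cf.endpoint_value, 1) == 4.8
        assert cf.values[1982] == 16.0

    def test_late_created_unit_is_not_assessable(self):
        cf = build_counterfactual(
            IndicatorSeries("Kilinochchi", Indicator.IMR, {2002: 3.9}),
            UnitMeta("Kilinochchi", "HIGH", creation_year=1984),
            StudyConfig(),
        )
        assert cf is None

    def test_baseline_only_series_is_not_assessable(self):
        cf = build_counterfactual(
            IndicatorSeries("X", Indicator.IMR, {1982: 20.0}),
            UnitMeta("X", "NONE"),
            StudyConfig(),
        )
        assert cf is None

    def test_endpoint_respects_unit_metadata(self):
        s = _district_series()
        s.observations[1999] = 12.0
        cf = build_counterfactual(
            s, UnitMeta("Vavuniya", "HIGH", mmr_endpoint_year=1999), StudyConfig()
        )
        assert cf.endpoint_year == 2002  # IMR endpoint unaffected
        s2 = IndicatorSeries("V", Indicator.MMR, dict(s.observations))
        cf2 = build_counterfactual(
            s2, UnitMeta("V", "HIGH", mmr_endpoint_year=1999), StudyConfig()
        )
        assert cf2.endpoint_year == 1999


class TestSensitivity:
    def test_zero_rate_panel_is_consistent_across_shapes(self):
        series = [IndicatorSeries("U", Indicator.IMR, {1975: 10, 1982: 10, 2002: 10})]
        meta = {"U": UnitMeta("U", "NONE")}
        results = sensitivity_analysis(series, meta, StudyConfig(), list(Shape))
        (r,) = results
        assert r.consistent and set(r.flags.values()) == {r.flags[Shape.COMPOUND]}

    def test_actual_below_every_projection_is_consistent(self):
        # at -0.03/yr every shape stays positive (linear minimum is 6.4);
        # an actual endpoint of 1.0 is below all four projections
        s = _district_series(rate_pre=-0.03, actual_end=1.0)
        results = sensitivity_analysis(
            [s], {"Vavuniya": UnitMeta("Vavuniya", "HIGH")}, StudyConfig(), list(Shape)
        )
        assert results[0].consistent
        assert set(results[0].flags.values()) == {Flag.BETTER}

    def test_actual_between_linear_and_compound_is_inconsistent(self):
        # projections at rate -0.058 over 20y: compound 4.84, linear -2.56;
        # an actual of 3.0 is worse than linear, better than compound
        s = _district_series(actual_end=3.0)
        results = sensitivity_analysis(
            [s],
            {"Vavuniya": UnitMeta("Vavuniya", "HIGH")},
            StudyConfig(),
            [Shape.COMPOUND, Shape.LINEAR],
        )
        assert not results[0].consistent

    def test_fewer_than_two_shapes_is_an_error(self):
        with pytest.raises(ValueError, match="two shapes"):
            sensitivity_analysis([], {}, StudyConfig(), [Shape.COMPOUND])
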