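"""Excitation kernel, baselines, expected-count and likelihood checks."""

import datetime
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import selfexcite as sx
from selfexcite.contagion import (
    BaselineModel,
    ContagionParams,
    excitation_series,
    poisson_log_likelihood,
)
from selfexcite.event_io import DailySeries


def make_series(counts, origin=datetime.date(2010, 1, 1)):
    import pandas as pd

    grid = pd.date_range(origin, periods=len(counts), freq="D")
    return DailySeries(
        origin=origin,
        counts=np.asarray(counts),
        weekday=grid.weekday.to_numpy(),
        month=grid.month.to_numpy(),
    )


class TestExcitationKernel:
    def test_closed_form_day_one(self):
        # independent evaluation: probability mass of Exp(T) in (0, 1]
        assert sx.excitation_probability(1, 13.2) == pytest.approx(
            1.0 - math.exp(-1.0 / 13.2), abs=1e-15
        )

    def test_vanishes_in_the_tail(self):
        assert sx.excitation_probability(10_000, 13.2) < 1e-300

    @pytest.mark.parametrize("t_excite", [1.0, 13.2, 100.0])
    def test_partial_sums_telescope(self, t_excite):
        k = np.arange(1, 2001)
        total = sx.excitation_probability(k, t_excite).sum()
        assert total == pytest.approx(1.0 - math.exp(-2000.0 / t_excite), abs=1e-12)

    @given(st.integers(min_value=1, max_value=400))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_strictly_decreasing_in_lag(self, delta):
        t = 13.2
        assert sx.excitation_probability(delta, t) > sx.excitation_probability(delta + 1, t)

    @given(
        st.floats(min_value=0.6, max_value=200.0),
        st.floats(min_value=1.01, max_value=3.0),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_day_one_mass_decreases_with_duration(self, t, factor):
        assert sx.excitation_probability(1, t) > sx.excitation_probability(1, t * factor)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sx.excitation_probability(0, 13.2)
        with pytest.raises(ValueError):
            sx.excitation_probability(1, 0.0)

    def test_series_matches_explicit_sum(self):
        counts = np.array([1, 0, 2, 0, 0, 1, 0, 0])
        t = 3.5
        s = excitation_series(counts, t)
        event_days = np.repeat(np.arange(len(counts)), counts)
        for day in range(len(counts)):
            prior = event_days[event_days < day]
            expect = sx.excitation_probability(day - prior, t).sum() if len(prior) else 0.0
            assert s[day] == pytest.approx(expect, abs=1e-12)


class TestBaseline:
    def test_running_mean_of_constant_is_constant(self):
        series = make_series(np.full(400, 3))
        n0 = sx.baseline_running_mean(series, bandwidth_days=150.0)
        assert np.allclose(n0, 3.0, atol=1e-9)

    def test_running_mean_is_linear_in_counts(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.3, size=600)
        series1 = make_series(counts)
        series2 = make_series(2 * counts)
        a = sx.baseline_running_mean(series1, 150.0)
        b = sx.baseline_running_mean(series2, 150.0)
        assert np.allclose(b, 2 * a, atol=1e-10)

    def test_running_mean_conserves_total_mass_approximately(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.2, size=2000)
        series = make_series(counts)
        n0 = sx.baseline_running_mean(series, 200.0)
        assert n0.sum() == pytest.approx(counts.sum(), rel=0.05)

    def test_narrow_bandwidth_warns(self):
        series = make_series(np.ones(100, dtype=int))
        with pytest.warns(UserWarning, match="bandwidth"):
            sx.baseline_running_mean(series, 20.0)

    def test_calendar_weights_mean_one_and_exposure_adjusted(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(0.5, size=730)
        series = make_series(counts)
        wd, mo = sx.estimate_calendar_weights(series)
        assert wd.shape == (7,) and mo.shape == (12,)
        assert wd.mean() == pytest.approx(1.0)
        assert mo.mean() == pytest.approx(1.0)

    def test_weights_do_not_change_mean_rate(self):
        series = make_series(np.ones(700, dtype=int))
        wd = np.array([0.5, 0.5, 0.5, 1.0, 1.5, 1.5, 1.5])
        base = BaselineModel(form="constant", params=(0.3,), weekday_weights=wd)
        n0 = base.evaluate(series)
        assert n0.mean() == pytest.approx(0.3, rel=0.01)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            BaselineModel(form="constant", params=(0.1,), weekday_weights=np.ones(6))
        with pytest.raises(ValueError):
            BaselineModel(form="constant", params=(0.1,), weekday_weights=np.full(7, 2.0))

    def test_linear_baseline_interpolates_endpoints(self):
        series = make_series(np.zeros(11, dtype=int))
        base = BaselineModel(form="linear", params=(0.2, 0.4))
        n0 = base.evaluate(series)
        assert n0[0] == pytest.approx(0.2)
        assert n0[-1] == pytest.approx(0.4)
        assert np.all(np.diff(n0) > 0)


class TestExpectedEvents:
    def params(self, n_sec=0.3, t=13.2, n0=0.1):
        return ContagionParams(n_sec, t, BaselineModel(form="constant", params=(n0,)))

    def test_no_history_gives_baseline(self):
        assert sx.expected_events(10, [], self.params()) == pytest.approx(0.1)

    def test_zero_branching_gives_baseline(self):
        assert sx.expected_events(10, [3, 7, 9], self.params(n_sec=0.0)) == pytest.approx(0.1)

    def test_one_prior_event_composes_with_kernel(self):
        expect = 0.1 + 0.3 * sx.excitation_probability(1, 13.2)
        assert sx.expected_events(5, [4], self.params()) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.1219, abs=2e-4)

    def test_history_contribution_is_additive(self):
        p = self.params()
        a, b = [1, 3], [2, 6]
        base = 0.1
        both = sx.expected_events(8, a + b, p) - base
        only_a = sx.expected_events(8, a, p) - base
        only_b = sx.expected_events(8, b, p) - base
        assert both == pytest.approx(only_a + only_b, abs=1e-12)

    def test_prior_on_or_after_day_rejected(self):
        with pytest.raises(ValueError):
            sx.expected_events(5, [5], self.params())


class TestLogLikelihood:
    def test_hand_computed_three_days(self):
        series = make_series([1, 0, 0])
        params = ContagionParams(0.0, 13.2, BaselineModel(form="constant", params=(0.1,)))
        # Poisson: log(0.1) - 0.1 - 0.1 - 0.1 = -2.6026
        assert sx.log_likelihood(series, params) == pytest.approx(
            math.log(0.1) - 0.3, abs=1e-12
        )

    def test_all_zero_counts(self):
        series = make_series([0, 0, 0, 0])
        params = ContagionParams(0.2, 5.0, BaselineModel(form="constant", params=(0.25,)))
        mu = sx.expected_series(series, params)
        assert sx.log_likelihood(series, params) == pytest.approx(-mu.sum())

    def test_zero_branching_equals_pure_poisson(self, null_series):
        params = ContagionParams(0.0, 13.2, BaselineModel(form="constant", params=(0.08,)))
        direct = poisson_log_likelihood(null_series.counts, np.full(null_series.n_days, 0.08))
        assert sx.log_likelihood(null_series, params) == pytest.approx(direct, abs=1e-9)

    def test_event_on_zero_mean_day_gives_minus_inf(self):
        series = make_series([1, 0])
        params = ContagionParams(0.3, 5.0, BaselineModel(form="constant", params=(0.0,)))
        assert sx.log_likelihood(series, params) == -math.inf

    def test_expected_series_reduces_to_baseline_without_history_effect(self, null_series):
        params = ContagionParams(0.0, 7.0, BaselineModel(form="constant", params=(0.08,)))
        assert np.allclose(sx.expected_series(null_series, params), 0.08)
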