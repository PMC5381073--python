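"""Evaluation metrics: efficiency, bands, response/recovery, covariance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microlv import (
    ObservedSeries,
    deviation_time,
    equilibrium_band,
    nash_sutcliffe,
    prey_release_covariance,
    recovery_time,
    response_time,
)


class TestNashSutcliffe:
    def test_perfect_fit_is_one(self):
        obs = np.array([1.0, 5.0, 2.0, 8.0])
        assert nash_sutcliffe(obs, obs) == 1.0

    def test_mean_predictor_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        pred = np.full_like(obs, obs.mean())
        assert nash_sutcliffe(pred, obs) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_example(self):
        # SSE = 4, SST = 2 -> E = 1 - 4/2 = -1
        assert nash_sutcliffe([1.0, 2.0, 5.0], [1.0, 2.0, 3.0]) == pytest.approx(-1.0)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(-1e6, 1e6))
    def test_invariant_to_common_shift(self, shift):
        obs = np.array([1.0, 4.0, 2.0, 9.0])
        pred = np.array([1.5, 3.0, 2.5, 8.0])
        e0 = nash_sutcliffe(pred, obs)
        e1 = nash_sutcliffe(pred + shift, obs + shift)
        assert e1 == pytest.approx(e0, rel=1e-6, abs=1e-9)

    def test_constant_observed_is_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            nash_sutcliffe([1.0, 2.0], [3.0, 3.0])


class TestEquilibriumBand:
    def test_constant_series(self):
        days = np.arange(20)
        band = equilibrium_band(days, np.full(20, 7.0), 7, 15)
        assert (band.low, band.high) == (7.0, 7.0)

    def test_min_max_envelope(self):
        days = np.arange(7, 15)
        values = np.array([10, 12, 11, 9, 10, 12, 11, 10], dtype=float)
        band = equilibrium_band(days, values, 7, 15)
        assert (band.low, band.high) == (9.0, 12.0)

    def test_empty_window_is_an_error(self):
        with pytest.raises(ValueError):
            equilibrium_band(np.arange(5), np.ones(5), 7, 15)
        with pytest.raises(ValueError, match="from_day"):
            equilibrium_band(np.arange(20), np.ones(20), 15, 7)


class TestResponseTime:
    def test_leaves_band_on_start_day(self):
        days = np.arange(20)
        values = np.full(20, 10.0)
        values[15:] = 5.0
        band = equilibrium_band(days, np.full(20, 10.0), 7, 15)
        assert response_time(days, values, band, 15) == 0

    def test_direct_count(self):
        days = np.arange(20)
        values = np.full(20, 10.0)
        values[17:] = 8.0  # first below band.low=9 on day 17
        from microlv import EquilibriumBand

        band = EquilibriumBand(low=9.0, high=12.0, from_day=7, to_day=15)
        assert response_time(days, values, band, 15) == 2

    def test_never_leaving_is_undefined(self):
        days = np.arange(20)
        from microlv import EquilibriumBand

        band = EquilibriumBand(low=0.0, high=100.0, from_day=7, to_day=15)
        assert response_time(days, np.full(20, 10.0), band, 15) is None

    def test_band_overlapping_scan_is_an_error(self):
        from microlv import EquilibriumBand

        band = EquilibriumBand(low=9.0, high=12.0, from_day=7, to_day=18)
        with pytest.raises(ValueError, match="overlaps"):
            response_time(np.arange(20), np.full(20, 10.0), band, 15)


class TestRecoveryTime:
    def band(self):
        from microlv import EquilibriumBand

        return EquilibriumBand(low=9.0, high=12.0, from_day=7, to_day=15)

    def test_already_inside_at_end(self):
        days = np.arange(40)
        rec = recovery_time(days, np.full(40, 10.0), self.band(), 32)
        assert rec.days == 0 and not rec.censored

    def test_direct_count(self):
        days = np.arange(40)
        values = np.full(40, 5.0)
        values[36:] = 10.0  # first in-band day is 36, disturbance ends day 32
        rec = recovery_time(days, values, self.band(), 32)
        assert rec.days == 4 and not rec.censored

    def test_censoring_never_fabricates_a_return(self):
        days = np.arange(40)
        rec = recovery_time(days, np.full(40, 5.0), self.band(), 32)
        assert rec.censored
        assert rec.days == rec.horizon == 39 - 32

    def test_reach_criterion_catches_a_jump_over_the_band(self):
        """A population stepping from below band.low to above band.high in
        one day recovers at the crossing under mode='reach' but would be
        missed for days by the inside-the-band reading."""
        days = np.arange(40)
        values = np.full(40, 2.0)
        values[34] = 20.0  # overshoot
        values[35:] = 30.0
        band_rec = recovery_time(days, values, self.band(), 32, mode="band")
        reach_rec = recovery_time(days, values, self.band(), 32, mode="reach")
        assert band_rec.censored
        assert reach_rec.days == 2 and not reach_rec.censored

    def test_reach_from_above(self):
        days = np.arange(40)
        values = np.full(40, 30.0)
        values[35:] = 11.0
        rec = recovery_time(days, values, self.band(), 32, mode="reach")
        assert rec.days == 3


class TestDeviationTime:
    def _observed_from(self, days, values):
        rows = [
            {"day": d, "replicate": r, "prey": v, "predator": v}
            for d, v in zip(days, values)
            for r in (1, 2, 3)
        ]
        return ObservedSeries(pd.DataFrame(rows))

    def test_identical_series_gives_zero(self):
        days = np.arange(30)
        values = np.full(30, 10.0)
        values[18:] = 5.0
        obs = self._observed_from(days, values)
        assert deviation_time(days, values, obs, "prey", 7, 15, 15) == 0.0

    def test_sign_convention_model_earlier_is_negative(self):
        """Model responding on day +1 and data on day +4 gives D_T = -3."""
        days = np.arange(30)
        model = np.full(30, 10.0)
        model[16:] = 5.0  # leaves band 1 day after start (day 15)
        data = np.full(30, 10.0)
        data[19:] = 5.0  # leaves band 4 days after start
        obs = self._observed_from(days, data)
        assert deviation_time(days, model, obs, "prey", 7, 15, 15) == -3.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_shift_oracle(self, k):
        """Observed series built by delaying the model by k days has D_T = -k."""
        days = np.arange(40)
        model = np.full(40, 10.0)
        model[20:] = 4.0
        shifted = np.full(40, 10.0)
        shifted[20 + k :] = 4.0
        obs = self._observed_from(days, shifted)
        assert deviation_time(days, model, obs, "predator", 7, 15, 15) == -float(k)

    def test_undefined_when_no_response(self):
        days = np.arange(30)
        model = np.full(30, 10.0)
        model[16:] = 5.0
        flat = np.full(30, 10.0)
        obs = self._observed_from(days, flat)
        assert deviation_time(days, model, obs, "prey", 7, 15, 15) is None


class TestPreyReleaseCovariance:
    def test_constant_predator_gives_zero(self):
        days = np.arange(10)
        prey = np.linspace(1, 10, 10)
        predator = np.full(10, 5.0)
        assert prey_release_covariance(days, prey, predator, (0, 10)) == 0.0

    def test_two_point_hand_computation(self):
        """After max-scaling, cov((0.2, 0.8), (0.9, 0.1)) = -0.24."""
        days = np.array([0, 1])
        prey = np.array([0.2, 0.8])
        predator = np.array([0.9, 0.1])
        cov = prey_release_covariance(days, prey, predator, (0, 2), scaling="none")
        assert cov == pytest.approx(-0.24)

    def test_symmetry_under_series_exchange(self):
        days = np.arange(6)
        a = np.array([1.0, 3.0, 2.0, 8.0, 5.0, 4.0])
        b = np.array([9.0, 2.0, 7.0, 1.0, 3.0, 6.0])
        assert prey_release_covariance(days, a, b, (0, 6)) == pytest.approx(
            prey_release_covariance(days, b, a, (0, 6))
        )

    def test_max_scaling_is_invariant_to_input_rescaling(self):
        days = np.arange(6)
        a = np.array([1.0, 3.0, 2.0, 8.0, 5.0, 4.0])
        b = np.array([9.0, 2.0, 7.0, 1.0, 3.0, 6.0])
        c0 = prey_release_covariance(days, a, b, (1, 5))
        c1 = prey_release_covariance(days, 1e8 * a, 17.0 * b, (1, 5))
        assert c1 == pytest.approx(c0, rel=1e-12)

    def test_short_window_is_an_error(self):
        with pytest.raises(ValueError, match="< 2"):
            prey_release_covariance(np.arange(5), np.ones(5), np.ones(5), (0, 1))
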