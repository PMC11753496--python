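import numpy as np
import pytest
from scipy.optimize import brentq

from serpinkin.constants import R_GAS, c_to_k
from serpinkin.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    NoTransitionError,
)
from serpinkin.io import load_ramp_tm
from serpinkin.melt import (
    RampSeries,
    TwoStateFit,
    build_ramp_series,
    fit_two_state,
    ramp_rate_activation_energy,
    ramp_series_from_table,
)
from serpinkin.simulate import ArrheniusRate, simulate_melt


def logistic_melt(tm=55.0, m=1.5, lo=45.0, hi=65.0, n=101):
    t = np.linspace(lo, hi, n)
    return t, 1.0 / (1.0 + np.exp((tm - t) / m))


class TestFitTwoState:
    def test_noiseless_sigmoid_recovered_exactly(self):
        t, y = logistic_melt()
        fit = fit_two_state(t, y, window_c=(45, 65))
        assert fit.converged
        assert fit.tm_c == pytest.approx(55.0, abs=1e-6)
        assert fit.width_c == pytest.approx(1.5, abs=1e-6)

    @pytest.mark.parametrize("scale,offset", [(2.0, 0.0), (0.5, 3.0), (10.0, -1.0)])
    def test_affine_invariance_of_tm(self, scale, offset):
        t, y = logistic_melt()
        base = fit_two_state(t, y, window_c=(45, 65)).tm_c
        # offset may push the signal maximum elsewhere; fix the window
        other = fit_two_state(t, scale * y + offset, window_c=(45, 65)).tm_c
        assert other == pytest.approx(base, abs=1e-6)

    def test_flat_trace_raises_no_transition(self):
        t = np.linspace(25, 90, 100)
        rng = np.random.default_rng(0)
        y = 1.0 + 0.01 * rng.standard_normal(100)
        with pytest.raises(NoTransitionError):
            fit_two_state(t, y, window_c=(25, 90))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_two_state(np.arange(5.0), np.arange(5.0))

    def test_simulated_melt_midpoint_matches_transcendental_oracle(self):
        # independent oracle: Tm solves A exp(-Ea/RTm) R Tm^2 / (v Ea) = ln 2
        rate = ArrheniusRate(1e43, 280e3)
        tm_oracle = brentq(
            lambda T: rate.prefactor * np.exp(-rate.ea_j_mol / (R_GAS * T))
            * R_GAS * T ** 2 / (1.0 * rate.ea_j_mol) - np.log(2.0),
            250.0, 450.0,
        )
        assert tm_oracle == pytest.approx(335.0, abs=0.5)  # ~335 K for these params
        from serpinkin.simulate import SimScheme, DEFAULT_SCHEME

        scheme = SimScheme(rate, DEFAULT_SCHEME.activation,
                           DEFAULT_SCHEME.reversion, DEFAULT_SCHEME.association)
        # the closed form is asymptotic in RT/Ea, so direct integration
        # differs by O(2RT/Ea) in the exponent (~0.06 K here)
        sim = simulate_melt(scheme, 1.0)
        assert sim.true_tm_k == pytest.approx(tm_oracle, abs=0.1)
        # the symmetric-sigmoid fit carries a known systematic offset on
        # this asymmetric kinetic transition; it is bounded and cancels in
        # the scan-rate regression
        fit = fit_two_state(sim.temperature_c, sim.signal)
        assert fit.converged
        assert abs(fit.tm_c - (sim.true_tm_k - 273.15)) < 4.0

    def test_calibrated_scheme_reproduces_observed_midpoint(self, default_scheme):
        sim = simulate_melt(default_scheme, 1.0)
        assert sim.true_tm_k - 273.15 == pytest.approx(58.6, abs=0.15)


class TestRampSeries:
    def _fit(self, tm_c, se=0.1):
        return TwoStateFit(tm_c, se, 1.5, (0, 0), (1, 0), 0.0, True, (25, 90), 100)

    def test_duplicate_rates_aggregated_to_mean(self):
        series = build_ramp_series(
            [(1.0, self._fit(55.0)), (1.0, self._fit(57.0)),
             (2.0, self._fit(58.0)), (4.0, self._fit(60.0))]
        )
        assert series.tm_k[0] == pytest.approx(c_to_k(56.0))

    def test_fewer_than_three_rates_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_ramp_series([(1.0, self._fit(55)), (2.0, self._fit(56))])

    def test_unconverged_fit_rejected(self):
        bad = TwoStateFit(np.nan, np.nan, np.nan, (0, 0), (0, 0), np.nan,
                          False, (25, 90), 100)
        with pytest.raises(DomainError):
            build_ramp_series([(1.0, bad), (2.0, self._fit(56)), (4.0, self._fit(58))])

    def test_packaged_wildtype_row_converts_to_kelvin(self):
        series = ramp_series_from_table(load_ramp_tm(), "M")
        assert list(series.v_k_per_min) == [0.5, 1, 2, 4]
        np.testing.assert_allclose(
            series.tm_k, [329.65, 331.75, 334.55, 336.15], atol=1e-9
        )


class TestRampRateEa:
    def test_wildtype_table_regression_matches_hand_ols(self):
        # frozen oracle: OLS of ln(v/Tm^2) on 1/Tm computed by hand on the
        # four wild-type (rate, midpoint) pairs gives Ea = 277.99 kJ/mol
        res = ramp_rate_activation_energy(
            ramp_series_from_table(load_ramp_tm(), "M"))
        assert res.ea_kj_mol == pytest.approx(277.99, abs=0.01)
        assert res.ea_kj_mol == pytest.approx(-res.slope * R_GAS / 1e3)

    def test_mutant_table_regression_matches_hand_ols(self):
        res = ramp_rate_activation_energy(
            ramp_series_from_table(load_ramp_tm(), "G192C"))
        assert res.ea_kj_mol == pytest.approx(308.69, abs=0.01)

    def test_invariant_to_rate_units(self):
        series_min = ramp_series_from_table(load_ramp_tm(), "M")
        series_sec = RampSeries(series_min.v_k_per_min / 60.0, series_min.tm_k,
                                series_min.tm_se_k)
        ea_min = ramp_rate_activation_energy(series_min).ea_kj_mol
        ea_sec = ramp_rate_activation_energy(series_sec).ea_kj_mol
        assert ea_sec == pytest.approx(ea_min, rel=1e-12)

    def test_lnv_mode_shifts_by_about_2rt(self):
        series = ramp_series_from_table(load_ramp_tm(), "M")
        kiss = ramp_rate_activation_energy(series, mode="kissinger").ea_kj_mol
        lnv = ramp_rate_activation_energy(series, mode="lnv").ea_kj_mol
        expected_shift = 2 * R_GAS * float(np.mean(series.tm_k)) / 1e3
        assert lnv - kiss == pytest.approx(expected_shift, rel=0.05)

    def test_non_monotone_series_flagged(self):
        series = RampSeries([0.5, 1, 2], c_to_k(np.array([56.0, 58.0, 57.0])),
                            np.full(3, np.nan))
        res = ramp_rate_activation_energy(series)
        assert "non-kinetic behaviour" in res.flags

    def test_constant_tm_rejected(self):
        series = RampSeries([0.5, 1, 2], c_to_k(np.array([56.0, 56.0, 56.0])),
                            np.full(3, np.nan))
        with pytest.raises(DegenerateInputError):
            ramp_rate_activation_energy(series)


def test_simulated_midpoints_increase_with_scan_rate(scheme_ea280):
    tms = [simulate_melt(scheme_ea280, v).true_tm_k for v in (0.5, 1, 2, 4)]
    assert np.all(np.diff(tms) > 0)
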