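"""Kinetic trace decomposition and rate-law fits."""
import math

import numpy as np
import pytest

from gp32filament.constants import Constants, DEFAULT_CONSTANTS
from gp32filament.errors import InsufficientDataError
from gp32filament.kinetics import (
    RateSeries,
    TimeExtensionTrace,
    compute_kd,
    decompose_binding_trace,
    decompose_dissociation_trace,
    fit_bell,
    fit_bimolecular,
    fit_exponential,
    fit_two_step,
    noise_sd,
)
from gp32filament.synthetic import (
    GeneratorSpec,
    gen_binding_trace,
    gen_dissociation_trace,
    gen_rate_series,
)

from conftest import TRI_AMPS, TRI_DURATION, TRI_RATES, TRI_X0


class TestFitExponential:
    def test_single_exponential_exact(self, noiseless_spec):
        # noncooperative dissociation: 200-nm elongation at 0.11 s^-1
        tr = gen_dissociation_trace(0.0, 200.0, 0.11, 80.0, noiseless_spec,
                                    x0=2500.0)
        fit = fit_exponential(tr, 1)
        assert fit.x_eq == pytest.approx(2500.0, rel=1e-8)
        assert fit.amplitudes[0] == pytest.approx(200.0, rel=1e-6)
        assert fit.rates[0] == pytest.approx(0.11, rel=1e-6)

    def test_double_exponential_exact(self, noiseless_spec):
        tr = gen_binding_trace(1000.0, (0.0, 150.0, 250.0), (1.0, 0.3, 0.01),
                               800.0, noiseless_spec)
        fit = fit_exponential(tr, 2)
        assert fit.rates[0] == pytest.approx(0.3, rel=1e-4)
        assert fit.rates[1] == pytest.approx(0.01, rel=1e-4)
        assert fit.amplitudes[0] == pytest.approx(150.0, rel=1e-4)
        assert fit.amplitudes[1] == pytest.approx(250.0, rel=1e-4)
        assert not fit.fallback

    def test_rates_returned_descending(self, noisy_spec):
        tr = gen_binding_trace(1000.0, (0.0, 100.0, 200.0), (1.0, 0.2, 0.01),
                               600.0, noisy_spec)
        fit = fit_exponential(tr, 2)
        assert fit.rates[0] > fit.rates[1]

    def test_constant_trace(self):
        t = np.arange(0.0, 50.0, 0.25)
        tr = TimeExtensionTrace(t, np.full_like(t, 1234.5))
        fit = fit_exponential(tr, 1)
        assert fit.constant
        assert fit.x_eq == pytest.approx(1234.5)
        np.testing.assert_array_equal(fit.amplitudes, 0.0)

    def test_close_rates_fall_back_to_single(self, noiseless_spec):
        # 1.2x rate separation is unresolvable: collapses to one rate
        tr = gen_binding_trace(1000.0, (0.0, 100.0, 100.0), (1.0, 0.1, 0.083),
                               200.0, GeneratorSpec(seed=31, noise_sd=2.0, dt=0.25))
        fit = fit_exponential(tr, 2)
        assert fit.fallback
        assert fit.n_rates == 1

    def test_too_short_trace_rejected(self):
        tr = TimeExtensionTrace(np.arange(5.0), np.arange(5.0))
        with pytest.raises(InsufficientDataError):
            fit_exponential(tr, 1)


class TestBindingDecomposition:
    def test_triphasic_noiseless(self, noiseless_spec):
        tr = gen_binding_trace(TRI_X0, TRI_AMPS, TRI_RATES, TRI_DURATION,
                               noiseless_spec)
        d = decompose_binding_trace(tr)
        assert d.present_phases == (1, 2, 3)
        np.testing.assert_allclose(d.amplitudes, TRI_AMPS, rtol=1e-3)
        np.testing.assert_allclose(d.rates, TRI_RATES, rtol=1e-3)

    def test_triphasic_noisy_recovery(self, noisy_spec):
        tr = gen_binding_trace(TRI_X0, TRI_AMPS, TRI_RATES, TRI_DURATION,
                               noisy_spec)
        d = decompose_binding_trace(tr)
        assert d.present_phases == (1, 2, 3)
        np.testing.assert_allclose(d.amplitudes, TRI_AMPS, rtol=0.05)
        np.testing.assert_allclose(d.rates, TRI_RATES, rtol=0.10)
        assert d.k1 >= d.k2 >= d.k3

    def test_equilibrium_identity(self, noisy_spec):
        tr = gen_binding_trace(TRI_X0, TRI_AMPS, TRI_RATES, TRI_DURATION,
                               noisy_spec)
        d = decompose_binding_trace(tr)
        assert d.x_eq - d.x_init == pytest.approx(sum(d.amplitudes), abs=1e-9)

    def test_biphasic_elongation_no_compaction(self, noisy_spec):
        # low-force regime: immediate two-phase elongation
        tr = gen_binding_trace(TRI_X0, (0.0, 120.0, 150.0), TRI_RATES,
                               TRI_DURATION, noisy_spec)
        d = decompose_binding_trace(tr)
        assert d.present_phases == (2, 3)
        assert d.dx1 == 0.0
        assert d.dx2 == pytest.approx(120.0, rel=0.05)
        assert d.dx3 == pytest.approx(150.0, rel=0.05)

    def test_monophasic_compaction(self, noisy_spec):
        # high-force / truncate regime: single-phase compaction
        tr = gen_binding_trace(TRI_X0, (-180.0, 0.0, 0.0), (0.25, 0.05, 0.005),
                               120.0, noisy_spec)
        d = decompose_binding_trace(tr)
        assert d.present_phases == (1,)
        assert d.dx1 == pytest.approx(-180.0, rel=0.05)
        assert d.k1 == pytest.approx(0.25, rel=0.10)
        assert d.dx2 == 0.0 and d.dx3 == 0.0

    def test_short_trace_rejected(self):
        tr = TimeExtensionTrace(np.arange(10.0), np.arange(10.0))
        with pytest.raises(InsufficientDataError):
            decompose_binding_trace(tr)


class TestDissociationDecomposition:
    def test_pure_linear(self, noisy_spec):
        tr = gen_dissociation_trace(-0.5, 0.0, 0.0, 300.0, noisy_spec,
                                    x0=2500.0)
        d = decompose_dissociation_trace(tr)
        assert d.mode == "linear"
        assert d.linear_slope == pytest.approx(-0.5, rel=0.01)
        assert d.normalized_slope < 0

    def test_linear_plus_exponential(self, noisy_spec):
        # overcrowding regime: rapid exponential then slow linear recompaction
        tr = gen_dissociation_trace(-0.4, 150.0, 0.15, 300.0, noisy_spec,
                                    x0=2500.0)
        d = decompose_dissociation_trace(tr)
        assert d.mode == "linear_plus_exponential"
        assert d.linear_slope == pytest.approx(-0.4, rel=0.05)
        assert d.exp_amplitude == pytest.approx(150.0, rel=0.05)
        assert d.exp_rate == pytest.approx(0.15, rel=0.05)

    def test_pure_exponential(self, noisy_spec):
        tr = gen_dissociation_trace(0.0, 200.0, 0.11, 60.0, noisy_spec,
                                    x0=2500.0)
        d = decompose_dissociation_trace(tr)
        assert d.mode == "exponential"
        assert d.exp_amplitude == pytest.approx(200.0, rel=0.05)
        assert d.exp_rate == pytest.approx(0.11, rel=0.05)

    def test_flat_trace_is_linear_zero_slope(self, noisy_spec):
        tr = gen_dissociation_trace(0.0, 0.0, 0.0, 120.0, noisy_spec,
                                    x0=2500.0)
        d = decompose_dissociation_trace(tr)
        assert d.mode == "linear"
        assert d.linear_slope == pytest.approx(0.0, abs=0.05)


class TestBellModel:
    def test_exact_recovery_negative_dx(self, noiseless_spec):
        # compaction rate decreasing with force: dx = -0.105 nm
        grid = np.linspace(10.0, 60.0, 11)
        series = gen_rate_series("bell", {"k0": 1.0, "delta_x": -0.105}, grid,
                                 noiseless_spec)
        fit = fit_bell(series)
        assert fit.delta_x == pytest.approx(-0.105, rel=1e-9)
        assert fit.k0 == pytest.approx(1.0, rel=1e-9)

    def test_exact_recovery_positive_dx(self, noiseless_spec):
        # slow-elongation (filament unwinding) rate: dx = +0.112 nm
        grid = np.linspace(10.0, 60.0, 11)
        series = gen_rate_series("bell", {"k0": 0.005, "delta_x": 0.112}, grid,
                                 noiseless_spec)
        fit = fit_bell(series)
        assert fit.delta_x == pytest.approx(0.112, rel=1e-9)

    def test_force_independent_rates_give_zero_dx(self):
        series = RateSeries([10.0, 20.0, 40.0], [0.3, 0.3, 0.3], kind="force")
        fit = fit_bell(series)
        assert fit.delta_x == pytest.approx(0.0, abs=1e-12)

    def test_rate_rescaling_only_moves_k0(self, noiseless_spec):
        grid = np.linspace(10.0, 60.0, 11)
        series = gen_rate_series("bell", {"k0": 1.0, "delta_x": -0.105}, grid,
                                 noiseless_spec)
        scaled = RateSeries(series.abscissa, 7.5 * series.rates, kind="force")
        fit, fit_scaled = fit_bell(series), fit_bell(scaled)
        assert fit_scaled.delta_x == pytest.approx(fit.delta_x, rel=1e-9)
        assert fit_scaled.k0 == pytest.approx(7.5 * fit.k0, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_bell(RateSeries([10.0, 20.0], [1.0, 0.5], kind="force"))

    def test_rate_ratio_over_force_span(self):
        # |dx| = 0.105 nm predicts a modest (3-4x) rate change over 50 pN
        ratio = math.exp(50.0 * 0.105 / DEFAULT_CONSTANTS.kBT)
        assert 3.0 <= ratio <= 4.0


class TestBimolecularAndTwoStep:
    def test_kd_from_printed_rates(self, noiseless_spec):
        grid = np.array([25.0, 50.0, 100.0, 200.0, 300.0])
        series = gen_rate_series("bimolecular",
                                 {"k_on": 0.0024, "k_off": 0.11}, grid,
                                 noiseless_spec)
        fit = fit_bimolecular(series)
        assert fit.k_on == pytest.approx(0.0024, rel=1e-9)
        assert fit.k_off == pytest.approx(0.11, rel=1e-9)
        assert fit.K_D == pytest.approx(45.83, abs=0.01)

    def test_zero_offrate_gives_zero_kd(self):
        series = RateSeries([10.0, 20.0], [0.024, 0.048], kind="concentration")
        fit = fit_bimolecular(series)
        assert fit.K_D == pytest.approx(0.0, abs=1e-12)

    def test_two_points_exact_line(self):
        series = RateSeries([10.0, 30.0], [0.2, 0.4], kind="concentration")
        fit = fit_bimolecular(series)
        assert fit.k_on == pytest.approx(0.01, rel=1e-9)
        assert fit.k_off == pytest.approx(0.1, rel=1e-9)

    def test_two_step_exact_recovery(self, noiseless_spec):
        grid = np.array([5.0, 20.0, 50.0, 100.0, 300.0, 600.0, 1000.0])
        series = gen_rate_series("two_step", {"k_b": 0.003, "k_c": 1.5}, grid,
                                 noiseless_spec)
        fit = fit_two_step(series)
        assert fit.k_b == pytest.approx(0.003, rel=1e-6)
        assert fit.k_c == pytest.approx(1.5, rel=1e-6)
        assert not fit.k_c_unbounded

    def test_two_step_asymptote(self, noiseless_spec):
        grid = np.array([5.0, 20.0, 50.0, 100.0, 300.0, 600.0, 1000.0])
        series = gen_rate_series("two_step", {"k_b": 0.003, "k_c": 1.5}, grid,
                                 noiseless_spec)
        fit = fit_two_step(series)
        assert fit.predict(1e9) == pytest.approx(fit.k_c, rel=1e-6)

    def test_two_step_reduces_to_bimolecular_slope(self, noiseless_spec):
        # k_c >> c k_b: two-step law is linear with slope k_b
        grid = np.array([5.0, 20.0, 50.0, 100.0, 200.0])
        series = gen_rate_series("two_step", {"k_b": 0.003, "k_c": 1e4}, grid,
                                 noiseless_spec)
        with pytest.warns(UserWarning, match="linear regime"):
            two = fit_two_step(series)
        bi = fit_bimolecular(series)
        assert two.k_b == pytest.approx(bi.k_on, rel=1e-3)
        assert two.k_c_unbounded


class TestComputeKd:
    @pytest.mark.parametrize("k_off, k_on, expected", [
        (0.11, 0.0024, 45.833),
        (0.0, 5.0, 0.0),
        (1.0, 1.0, 1.0),
    ])
    def test_ratio(self, k_off, k_on, expected):
        assert compute_kd(k_off, k_on) == pytest.approx(expected, abs=1e-3)

    def test_nonpositive_on_rate_rejected(self):
        with pytest.raises(ValueError):
            compute_kd(0.1, 0.0)


def test_noise_sd_estimator_matches_generator():
    rng = np.random.default_rng(7)
    x = np.cumsum(np.zeros(4000)) + rng.normal(0.0, 5.0, 4000)
    assert noise_sd(x) == pytest.approx(5.0, rel=0.1)
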