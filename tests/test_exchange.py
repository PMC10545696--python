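"""Diffusion-limited exchange: series, delayed exponential, calibration."""

import math

import numpy as np
import pytest

import gatefit as gf
from gatefit.exchange import T0_OVER_TAU
from gatefit.trace import Trace

UM = 1e-6


class TestGeometry:
    def test_delay_ratio_is_ln_4_over_pi(self):
        assert T0_OVER_TAU == pytest.approx(math.log(4 / math.pi), rel=1e-15)
        assert round(T0_OVER_TAU, 2) == 0.24

    def test_tau_from_geometry_formula_and_roundtrip(self):
        L, D = 5e-3, 1.96e-5
        tau = gf.tau_from_geometry(L, D)
        assert tau == pytest.approx(4 * L * L / (D * math.pi**2), rel=1e-15)
        assert gf.length_from_tau(tau, D) == pytest.approx(L, rel=1e-12)

    def test_quadratic_and_inverse_scaling(self):
        tau = gf.tau_from_geometry(1e-3, 1e-5)
        assert gf.tau_from_geometry(1e-3 * math.sqrt(2), 1e-5) == pytest.approx(
            2 * tau, rel=1e-12
        )
        assert gf.tau_from_geometry(1e-3, 2e-5) == pytest.approx(tau / 2, rel=1e-12)

    def test_rescale_tau_between_molecules(self):
        """1.1 ms K+ tau maps to ~4.9 ms for a cyclic nucleotide."""
        tau = gf.rescale_tau(1.1e-3, gf.DIFFUSION_COEFFICIENTS["K+"],
                             gf.DIFFUSION_COEFFICIENTS["cAMP"])
        assert tau == pytest.approx(1.1e-3 * 1.96 / 0.44, rel=1e-12)
        assert tau == pytest.approx(4.9e-3, rel=0.01)
        assert gf.rescale_tau(2.0, 1e-5, 1e-5) == 2.0
        assert gf.rescale_tau(2.0, 1e-5, 5e-6) == pytest.approx(4.0)


class TestConcentrationTimeCourse:
    em = gf.ExchangeModel.from_tau(c1=150e-3, c2=120e-3, tau=2e-3)

    def test_series_boundary_values(self):
        assert gf.series_concentration(self.em, 0.0) == self.em.c1
        amp = abs(self.em.c1 - self.em.c2)
        assert abs(gf.series_concentration(self.em, 10 * self.em.tau)
                   - self.em.c2) < 1e-4 * amp

    def test_series_close_to_delayed_exponential_at_tau(self):
        amp = abs(self.em.c1 - self.em.c2)
        diff = abs(gf.series_concentration(self.em, self.em.tau)
                   - gf.approx_concentration(self.em, self.em.tau))
        assert diff < 0.01 * amp

    def test_series_vs_approx_within_2pct_beyond_half_tau(self):
        t = np.linspace(0.5 * self.em.tau, 8 * self.em.tau, 400)
        amp = abs(self.em.c1 - self.em.c2)
        diff = np.abs(np.array(gf.series_concentration(self.em, t))
                      - gf.approx_concentration(self.em, t))
        assert diff.max() < 0.02 * amp
        # error is maximal near the delay and decays monotonically after
        t2 = np.linspace(1.5 * self.em.t0, 8 * self.em.tau, 200)
        d2 = np.abs(np.array(gf.series_concentration(self.em, t2))
                    - gf.approx_concentration(self.em, t2))
        assert np.all(np.diff(d2) <= 1e-12 * amp + 1e-30)

    def test_approx_holds_c1_before_delay(self):
        assert gf.approx_concentration(self.em, 0.0) == self.em.c1
        assert gf.approx_concentration(self.em, self.em.t0) == pytest.approx(
            self.em.c1, rel=1e-12
        )

    def test_strict_zero_branch_reproduces_published_piecewise_form(self):
        em = gf.ExchangeModel.from_tau(c1=0.0, c2=1e-4, tau=2e-3)
        assert gf.approx_concentration(em, 0.5 * em.t0, strict_zero_branch=True) == 0.0
        assert gf.approx_concentration(em, 0.5 * em.t0) == 0.0  # c1 = 0 branch agrees


class TestExchangeFit:
    @staticmethod
    def _k_jump_trace(tau, noise_sd=0.0, seed=None, dt=1e-4, dur=None):
        dur = dur or 12 * tau
        t = np.arange(int(dur / dt)) * dt
        t0 = tau * T0_OVER_TAU
        current = -200.0 - 50.0 * np.exp(-np.maximum(t - t0, 0.0) / tau)
        if noise_sd:
            rng = np.random.default_rng(seed)
            current = current + rng.normal(0, noise_sd, t.size)
        return Trace(time=t, current=current)

    def test_noiseless_tau_recovery(self):
        fit = gf.fit_exchange_tau(self._k_jump_trace(1.1e-3))
        assert fit.success and not fit.low_confidence
        assert abs(fit.tau / 1.1e-3 - 1) < 1e-3
        assert fit.t0 == pytest.approx(fit.tau * T0_OVER_TAU)

    def test_slow_patch_recovery_with_noise(self):
        """tau = 18.7 ms with 1% amplitude noise recovered within 5%."""
        trace = self._k_jump_trace(18.7e-3, noise_sd=0.5, seed=42)
        fit = gf.fit_exchange_tau(trace)
        assert abs(fit.tau / 18.7e-3 - 1) < 0.05

    def test_flat_trace_flags_low_confidence(self):
        t = np.arange(500) * 1e-4
        rng = np.random.default_rng(0)
        trace = Trace(time=t, current=rng.normal(-100.0, 0.5, t.size))
        fit = gf.fit_exchange_tau(trace)
        assert fit.low_confidence


class TestCorrectProtocol:
    def test_tiny_tau_limit_recovers_rectangular_protocol(self, pulse_protocol):
        corrected = gf.correct_protocol(pulse_protocol, 1e-9, dt=5e-4)
        nominal = gf.nominal_concentration(pulse_protocol, dt=5e-4)
        assert np.abs(corrected.conc - nominal.conc).max() < 1e-12

    def test_long_step_reaches_target(self):
        tau = 2e-3
        proto = gf.complex_protocol([(0.0, 5 * tau), (1e-4, 10 * tau)])
        trace = gf.correct_protocol(proto, tau, dt=5e-4)
        assert abs(trace.conc[-1] - 1e-4) < 1e-4 * 1e-4

    def test_incomplete_opposite_steps_chain_in_closed_form(self):
        """An up/down pair of duration tau peaks at 1 - exp(-(1 - t0/tau))."""
        tau = 4e-3
        amp = 1e-4
        proto = gf.complex_protocol([(0.0, 5 * tau), (amp, tau), (0.0, 3 * tau)])
        trace = gf.correct_protocol(proto, tau, dt=1e-5)
        expected_peak = amp * (1 - math.exp(-(1 - T0_OVER_TAU)))
        assert trace.conc.max() == pytest.approx(expected_peak, rel=5e-3)
        assert expected_peak == pytest.approx(0.5316 * amp, rel=1e-3)

    def test_output_bounded_by_nominal_levels(self, pulse_protocol):
        trace = gf.correct_protocol(pulse_protocol, 18.7e-3, dt=5e-4)
        assert trace.conc.min() >= 0.0
        assert trace.conc.max() <= pulse_protocol.levels.max() + 1e-18

    def test_single_step_equals_approx_concentration(self):
        tau = 3e-3
        proto = gf.complex_protocol([(1e-4, 0.05)])
        trace = gf.correct_protocol(proto, tau, dt=5e-4)
        em = gf.ExchangeModel.from_tau(c1=1e-4, c2=1e-4, tau=tau)
        # first segment starts pre-equilibrated at its own level
        assert np.abs(trace.conc - em.c2).max() < 1e-18

        proto2 = gf.complex_protocol([(0.0, 0.025), (1e-4, 0.05)])
        trace2 = gf.correct_protocol(proto2, tau, dt=5e-4)
        em2 = gf.ExchangeModel.from_tau(c1=0.0, c2=1e-4, tau=tau)
        t_rel = trace2.time[50:] + trace2.dt / 2 - 0.025
        expected = gf.approx_concentration(em2, t_rel)
        assert np.abs(trace2.conc[50:] - expected).max() < 1e-18

    def test_segment_shorter_than_dt_rejected(self):
        proto = gf.complex_protocol([(1e-4, 1e-4)])
        with pytest.raises(ValueError):
            gf.correct_protocol(proto, 1e-3, dt=5e-4)
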