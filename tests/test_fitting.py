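"""Global fitting, uncertainty quantification and model ranking."""

import numpy as np
import pytest
import scipy.optimize

import gatefit as gf
from gatefit.fitting import FitError, FitResult
from gatefit.propagate import propagate_piecewise

UM = 1e-6


class TestObjectiveSSR:
    def test_identical_traces_give_zero(self):
        po = np.random.default_rng(0).uniform(0, 1, 50)
        assert gf.objective_ssr(po, po) == 0.0

    def test_constant_offset(self):
        po = np.full(30, 0.4)
        assert gf.objective_ssr(po, po + 0.1) == pytest.approx(30 * 0.01)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)
        assert gf.objective_ssr(a, b) == pytest.approx(
            gf.objective_ssr(a[::-1], b[::-1])
        )

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(FitError):
            gf.objective_ssr(np.zeros(10), np.zeros(11))


class TestCorrelationMatrix:
    def test_identity_cov(self):
        assert np.allclose(gf.correlation_matrix(np.eye(3)), np.eye(3))

    def test_perfectly_correlated_pair(self):
        corr = gf.correlation_matrix(np.array([[4.0, 2.0], [2.0, 1.0]]))
        assert corr[0, 1] == pytest.approx(1.0)

    def test_invariant_under_diagonal_rescaling(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T
        d = np.diag([3.0, 0.5, 10.0])
        assert np.allclose(
            gf.correlation_matrix(cov), gf.correlation_matrix(d @ cov @ d)
        )

    def test_zero_variance_flagged_as_nan(self):
        corr = gf.correlation_matrix(np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert np.isnan(corr[0, 1]) and np.isnan(corr[1, 1])


class TestReducedSSR:
    def test_arithmetic(self):
        assert gf.reduced_ssr(4.4, 23, 1) == pytest.approx(0.2)
        assert gf.reduced_ssr(0.0, 23, 4) == 0.0

    def test_monotone_in_parameter_count(self):
        vals = [gf.reduced_ssr(1.0, 23, k) for k in range(1, 22)]
        assert np.all(np.diff(vals) > 0)

    def test_underdetermined_rejected(self):
        with pytest.raises(FitError):
            gf.reduced_ssr(1.0, 4, 4)


def _stub_fit(label, S, k, n_jumps, data_hash="h", converged=True,
              underdetermined=False):
    kk = max(k, 1)
    return FitResult(
        model_label=label, param_names=tuple(f"p{i}" for i in range(kk)),
        theta_hat=np.ones(kk), sd=np.zeros(kk), cov=np.eye(kk),
        corr=np.eye(kk), S=S, sigma2_bar=1.0, chi2=S, n_points=100, k=k,
        n_jumps=n_jumps, reduced_ssr=S / (n_jumps - k) if n_jumps > k else None,
        converged=converged, n_iter=5, data_hash=data_hash,
        underdetermined=underdetermined,
    )


class TestRankModels:
    def test_equal_s_penalises_extra_parameters(self):
        fits = [_stub_fit("big", 1.0, 6, 23), _stub_fit("small", 1.0, 2, 23)]
        ranking = gf.rank_models(fits)
        assert [f.model_label for f in ranking.ranked] == ["small", "big"]

    def test_single_fit_passes_through(self):
        fit = _stub_fit("only", 1.0, 2, 23)
        ranking = gf.rank_models([fit])
        assert ranking.ranked == [fit]
        assert ranking.best is fit

    def test_underdetermined_fits_never_ranked(self):
        fits = [
            _stub_fit("ok", 2.0, 2, 23),
            _stub_fit("und", 0.1, 2, 23, underdetermined=True),
            _stub_fit("overpar", 0.1, 23, 23),
        ]
        ranking = gf.rank_models(fits)
        assert [f.model_label for f in ranking.ranked] == ["ok"]
        assert {f.model_label for f in ranking.unranked} == {"und", "overpar"}

    def test_heterogeneous_data_rejected(self):
        fits = [_stub_fit("a", 1.0, 2, 23, data_hash="x"),
                _stub_fit("b", 1.0, 2, 23, data_hash="y")]
        with pytest.raises(FitError):
            gf.rank_models(fits)


class TestHillFit:
    def test_exact_hill_data_recovered(self):
        c = np.concatenate([[0.0], np.geomspace(1e-7, 1e-5, 8), [1e-4]])
        resp = np.zeros_like(c)
        resp[1:-1] = 1.0 / (1.0 + (2e-6 / c[1:-1]) ** 2)
        resp[-1] = 1.0  # saturating point used for normalisation only
        fit = gf.hill_fit(c, resp)
        assert fit.ec50 == pytest.approx(2e-6, rel=1e-4)
        assert fit.hill_n == pytest.approx(2.0, rel=1e-4)
        assert fit.response(fit.ec50) == pytest.approx(0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            gf.hill_fit([0.0, 1e-6, 1e-5], [0.0, 0.5, 1.0])

    def test_quasi_equilibrium_cooperative_staircase_has_steep_slope(
        self, m44, m44_truth
    ):
        """Two sequential binding steps make the fitted Hill n exceed 1."""
        proto = gf.staircase_protocol(0.3 * UM, 300 * UM, 10, 1.0, "up")
        conc = gf.correct_protocol(proto, 1.1e-3, dt=5e-4)
        trace = gf.simulate_deterministic(
            m44, m44_truth, conc,
            p0=gf.stationary_distribution(m44, m44_truth, 0.0),
        )
        summary = gf.late_response(trace, proto, {"last_fraction": 0.05})
        fit = gf.hill_fit(summary["conc"].to_numpy(),
                          summary["response"].to_numpy())
        assert fit.hill_n > 1.0


class TestGlobalFit:
    def test_noiseless_self_fit_recovers_parameters(self, m44, m44_truth):
        levels = [0.5, 100, 2, 25, 0.0, 8]
        proto = gf.complex_protocol([(l * UM, 0.2) for l in levels])
        conc = gf.correct_protocol(proto, 1.1e-3, dt=5e-4)
        data = gf.simulate_deterministic(m44, m44_truth, conc)
        fit = gf.global_fit(m44, conc, data, theta0=m44_truth * [0.3, 3, 3, 0.3],
                            n_jumps=proto.n_jumps())
        assert fit.converged
        assert np.abs(fit.theta_hat / m44_truth - 1).max() < 0.01
        assert fit.S < 1e-10 * fit.n_points
        assert not gf.underdetermination_report(fit)

    def test_co_recovery_with_50x_slower_exchange(self, co_model, co_truth):
        """Exchange 50x slower than activation, noiseless: errors << 1%."""
        c_step = 1e-4
        tau_a = 1.0 / (co_truth[0] * c_step + co_truth[1])
        tau_s = 50 * tau_a
        proto = gf.complex_protocol([(0.0, 0.02), (c_step, 0.3), (0.0, 0.3)])
        conc = gf.correct_protocol(proto, tau_s, dt=5e-4)
        data = gf.simulate_deterministic(co_model, co_truth, conc)
        fit = gf.global_fit(co_model, conc, data, theta0=co_truth * [3, 0.3],
                            n_jumps=proto.n_jumps())
        assert fit.converged
        assert np.abs(fit.theta_hat / co_truth - 1).max() < 0.01

    def test_rectangular_protocol_fits_slow_exchange_data_worse(
        self, co_model, co_truth
    ):
        c_step = 1e-4
        tau_s = 10e-3
        proto = gf.complex_protocol([(0.0, 0.02), (c_step, 0.25), (0.0, 0.25)])
        conc = gf.correct_protocol(proto, tau_s, dt=5e-4)
        rect = gf.nominal_concentration(proto, dt=5e-4)
        data = gf.simulate_deterministic(co_model, co_truth, conc)
        fit_corr = gf.global_fit(co_model, conc, data, theta0=co_truth * [3, 0.3])
        fit_rect = gf.global_fit(co_model, rect, data, theta0=co_truth * [3, 0.3])
        assert fit_rect.S > 100 * fit_corr.S

    def test_agrees_with_scipy_least_squares_oracle(self, co_model, co_truth):
        """Independent optimiser on the same objective finds the same rates."""
        c_step = 1e-4
        proto = gf.complex_protocol([(0.0, 0.02), (c_step, 0.1), (0.0, 0.1)])
        conc = gf.correct_protocol(proto, 3e-3, dt=5e-4)
        data = gf.simulate_stochastic(co_model, co_truth, conc, 1000, seed=9)

        def resid(x):
            po, _ = propagate_piecewise(co_model, np.exp(x), conc.conc, conc.dt)
            return po - data.po

        oracle = scipy.optimize.least_squares(
            resid, np.log(co_truth * [3, 0.3]), method="lm", xtol=1e-14
        )
        fit = gf.global_fit(co_model, conc, data, theta0=co_truth * [3, 0.3])
        assert np.abs(fit.theta_hat / np.exp(oracle.x) - 1).max() < 1e-3

    def test_fixed_parameters_are_clamped(self, co_model, co_truth):
        c_step = 1e-4
        proto = gf.complex_protocol([(0.0, 0.02), (c_step, 0.1), (0.0, 0.1)])
        conc = gf.correct_protocol(proto, 1e-3, dt=5e-4)
        data = gf.simulate_deterministic(co_model, co_truth, conc)
        fit = gf.global_fit(co_model, conc, data, theta0=co_truth * [5, 1],
                            fixed={"k_close": co_truth[1]})
        assert fit.k == 1 and fit.param_names == ("k_open",)
        assert fit.fixed["k_close"] == co_truth[1]
        assert abs(fit.theta_hat[0] / co_truth[0] - 1) < 1e-3

    def test_invalid_theta0_rejected(self, co_model):
        conc = gf.nominal_concentration(
            gf.complex_protocol([(1e-4, 0.05)]), dt=5e-4
        )
        data = conc.replace(po=np.zeros(conc.n))
        with pytest.raises(FitError):
            gf.global_fit(co_model, conc, data, theta0=[1e6])
        with pytest.raises(FitError):
            gf.global_fit(co_model, conc, data, theta0=[-1.0, 10.0])


class TestUnderdeterminationReport:
    def test_identity_corr_reports_nothing(self):
        fit = _stub_fit("x", 1.0, 3, 23)
        assert gf.underdetermination_report(fit) == []

    def test_threshold_one_only_exact_pairs(self):
        fit = _stub_fit("x", 1.0, 3, 23)
        fit.corr = np.array([[1.0, 0.9995, -1.0],
                             [0.9995, 1.0, 0.5],
                             [-1.0, 0.5, 1.0]])
        pairs = gf.underdetermination_report(fit, threshold=1.0)
        assert pairs == [("p0", "p2", -1.0)]
        assert len(gf.underdetermination_report(fit, threshold=0.999)) == 2

    def test_ridge_degeneracy_detected_in_real_fit(self, m44):
        """A fleeting intermediate leaves only the k-1/k2 ratio determined."""
        truth = np.array([2e6, 1000.0, 1e8, 50.0])
        segs = [(0.0, 0.2), (100 * UM, 0.3), (3 * UM, 0.3), (0.0, 0.3),
                (100 * UM, 0.2), (1 * UM, 0.3), (0.0, 0.3),
                (100 * UM, 0.1), (10 * UM, 0.3), (0.0, 0.3),
                (100 * UM, 0.3), (0.3 * UM, 0.3), (0.0, 0.3)]
        proto = gf.complex_protocol(segs)
        conc = gf.correct_protocol(proto, 1.1e-3, dt=5e-4)
        data = gf.simulate_deterministic(m44, truth, conc)
        fit = gf.global_fit(m44, conc, data, theta0=truth * [0.5, 2, 0.5, 2],
                            n_jumps=proto.n_jumps())
        flagged = {frozenset(p[:2]) for p in gf.underdetermination_report(fit)}
        assert frozenset(("k-1", "k2")) in flagged
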