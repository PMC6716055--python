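"""Riesz-Feller operator, stationarity residual, and tail-exponent estimation."""

import numpy as np
import pytest

from levyhrv import (
    ContractError,
    ControlPolynomial,
    GridFunction,
    InsufficientDataError,
    ParameterError,
    StableLaw,
    cauchy_quartic_stationary_pdf,
    fit_tail_exponent,
    predicted_mu,
    riesz_feller_apply,
    stationarity_residual,
)


class TestPredictedMu:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(1.5, 0, 2.5), (1.5, 1, 4.5), (2.0, 0, 3.0), (2.0, 1, 5.0)]
    )
    def test_values(self, alpha, n, expected):
        assert predicted_mu(alpha, n) == expected

    def test_finite_variance_threshold(self):
        # mu crosses 3 exactly where alpha + 2n = 2; any nonlinear control
        # order n >= 1 pushes the tail into the finite-second-moment regime
        assert predicted_mu(2.0, 0) == 3.0
        for alpha in (1.3, 1.5, 1.7):
            assert predicted_mu(alpha, 0) < 3.0
            assert predicted_mu(alpha, 1) > 3.0


class TestRieszFeller:
    @pytest.mark.parametrize("alpha", [1.2, 1.5, 1.7])
    def test_spectral_and_gl_routes_agree(self, alpha, gaussian_grid):
        a = riesz_feller_apply(gaussian_grid, alpha, method="spectral").values
        b = riesz_feller_apply(gaussian_grid, alpha, method="gl").values
        rel = np.linalg.norm(a - b) / np.linalg.norm(a)
        assert rel < 1e-3

    def test_routes_agree_below_alpha_one(self, gaussian_grid):
        # for alpha < 1 the operator output decays like |x|^-(1+alpha), so the
        # finite-domain boundary treatments of the two routes diverge sooner
        a = riesz_feller_apply(gaussian_grid, 0.8, method="spectral").values
        b = riesz_feller_apply(gaussian_grid, 0.8, method="gl").values
        assert np.linalg.norm(a - b) / np.linalg.norm(a) < 3e-2

    def test_cosine_eigenfunction(self):
        # cos(k x) is an eigenfunction with eigenvalue -|k|^alpha on a
        # periodic grid
        n = 2**10
        x = np.linspace(-np.pi * (1 - 2 / n) / (2 / n) * (2 / n), 0, 1)  # placeholder
        L = np.pi * 8
        x = np.linspace(-L, L, n, endpoint=False)
        x = x + (x[1] - x[0]) / 2  # symmetric about 0
        k = 2.0
        f = GridFunction(x, np.cos(k * x) + 1.0)  # shift to keep values >= 0
        for alpha in (0.9, 1.5):
            out = riesz_feller_apply(f, alpha, method="spectral").values
            np.testing.assert_allclose(out, -(k**alpha) * np.cos(k * x), atol=1e-8)

    def test_alpha_near_two_approaches_second_derivative(self, gaussian_grid):
        near = riesz_feller_apply(gaussian_grid, 1.999, method="spectral").values
        exact = riesz_feller_apply(gaussian_grid, 2.0).values
        core = np.abs(gaussian_grid.grid) < 5
        assert np.max(np.abs(near[core] - exact[core])) < 5e-3

    def test_alpha_domain(self, gaussian_grid):
        with pytest.raises(ParameterError):
            riesz_feller_apply(gaussian_grid, 0.0)
        with pytest.raises(ParameterError):
            riesz_feller_apply(gaussian_grid, 2.5)


def _grid_pdf(fn, L=60.0, n=2**13):
    x = np.linspace(-L, L, n, endpoint=False)
    x = x + (x[1] - x[0]) / 2
    v = fn(x)
    v = v / np.trapezoid(v, x)
    return GridFunction(x, v)


class TestStationarityResidual:
    def test_ou_gaussian_is_stationary(self):
        # alpha=2, linear control: the classical OU stationary density
        lam0, sigma2 = 0.8, 1.0
        var = sigma2 / lam0
        g = _grid_pdf(lambda x: np.exp(-(x**2) / (2 * var)), L=30.0)
        control = ControlPolynomial(lambda0=lam0)
        law = StableLaw(2.0, 1.0)
        r_true = stationarity_residual(g, control, law, region=(1.0, 10.0))
        wrong = _grid_pdf(lambda x: np.exp(-(x**2) / (2 * 2.0 * var)), L=30.0)
        r_wrong = stationarity_residual(wrong, control, law, region=(1.0, 10.0))
        assert r_true < 0.02
        assert r_wrong > 10 * r_true

    def test_exact_cauchy_quartic_solution(self):
        # closed-form stationary law for alpha=1, cubic drift: residual must
        # be tiny, and far smaller than grafted wrong-tail candidates
        law = StableLaw(1.0, 1.0)
        control = ControlPolynomial(lambda2n=1.0, order_n=1)
        g = _grid_pdf(lambda x: cauchy_quartic_stationary_pdf(x), L=200.0, n=2**15)
        r = stationarity_residual(g, control, law, region=(2.0, 50.0))
        assert r < 1e-3

        def grafted(m):
            def f(x):
                base = cauchy_quartic_stationary_pdf(x)
                t = np.abs(x) > 2.0
                amp = cauchy_quartic_stationary_pdf(2.0) * 2.0**m
                out = np.where(t, amp * np.abs(x) ** (-m), base)
                return out

            return _grid_pdf(f, L=200.0, n=2**15)

        for m in (3.0, 5.0):
            r_wrong = stationarity_residual(
                grafted(m), control, law, region=(3.0, 50.0)
            )
            assert r_wrong > 20 * r

    def test_contract_checks(self):
        x = np.linspace(-10, 10, 2**10, endpoint=False)
        x = x + (x[1] - x[0]) / 2
        control = ControlPolynomial(lambda0=1.0)
        law = StableLaw(1.5, 1.0)
        with pytest.raises(ContractError):
            stationarity_residual(
                GridFunction(x, np.zeros_like(x)), control, law
            )
        with pytest.raises(ContractError):
            stationarity_residual(
                GridFunction(x, np.full_like(x, 10.0)), control, law
            )


class TestTailFit:
    def _pareto(self, mu, n, seed, scale=1.0):
        # inverse-CDF sampling of an exact Pareto with density ~ x^-mu
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=n)
        return scale * u ** (-1.0 / (mu - 1.0))

    def test_recovers_exact_pareto(self):
        x = self._pareto(3.0, 100_000, seed=5)
        fit = fit_tail_exponent(x, window=(0.9, 0.9999))
        assert fit.mu_hat == pytest.approx(3.0, abs=0.1)
        assert fit.covers(3.0)
        assert fit.mu_loglog == pytest.approx(3.0, abs=0.3)

    def test_scale_invariance(self):
        x = self._pareto(2.5, 50_000, seed=6)
        a = fit_tail_exponent(x, window=(0.9, 0.9999))
        b = fit_tail_exponent(1234.5 * x, window=(0.9, 0.9999))
        assert a.mu_hat == pytest.approx(b.mu_hat, rel=1e-9)
        assert a.n_tail == b.n_tail

    def test_stable_samples_recover_density_tail(self):
        from levyhrv import sample_stable

        x = sample_stable(StableLaw(1.5, 1.0), 800_000, seed=7)
        # the deep window used by the tail-law experiments: the pre-asymptotic
        # regime of the stable density biases shallower windows upward
        fit = fit_tail_exponent(x, window=(0.999, 0.99995))
        assert fit.covers(2.5)
        assert fit.mu_hat == pytest.approx(2.5, abs=0.15)

    def test_insufficient_data_paths(self):
        with pytest.raises(InsufficientDataError):
            fit_tail_exponent(np.ones(100))
        x = self._pareto(3.0, 20_000, seed=8)
        with pytest.raises(InsufficientDataError):
            fit_tail_exponent(x, window=(0.999, 0.9999))

    def test_summary_and_json(self):
        x = self._pareto(3.0, 50_000, seed=9)
        fit = fit_tail_exponent(x, window=(0.9, 0.9999))
        assert "mu_hat" in fit.to_json()
        assert "IPL tail fit" in fit.summary()
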