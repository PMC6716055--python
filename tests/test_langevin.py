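"""Euler-Maruyama integration of the controlled Lévy-driven dynamics."""

import numpy as np
import pytest

from levyhrv import (
    ControlPolynomial,
    DataError,
    IntegrationError,
    ParameterError,
    SimulationConfig,
    StableLaw,
    drift,
    ensemble_second_moment,
    integrate,
)
from levyhrv.stable import _cms_unit


class TestDrift:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 0.0), (2.0, -10.0), (-2.0, 10.0)],
    )
    def test_cubic_control_arithmetic(self, value, expected):
        control = ControlPolynomial(lambda0=1.0, lambda2n=1.0, order_n=1)
        assert drift(value, control) == expected

    def test_odd_and_restoring(self):
        control = ControlPolynomial(lambda0=0.3, lambda2n=0.7, order_n=2)
        v = np.linspace(-3, 3, 41)
        d = drift(v, control)
        np.testing.assert_allclose(d, -drift(-v, control))
        nz = v != 0
        assert np.all(np.sign(d[nz]) == -np.sign(v[nz]))

    def test_invalid_controls(self):
        with pytest.raises(ParameterError):
            ControlPolynomial(lambda0=-0.1)
        with pytest.raises(ParameterError):
            ControlPolynomial(order_n=1, lambda2n=0.0)
        # free Lévy flight is a legal configuration
        ControlPolynomial(lambda0=0.0, lambda2n=0.0, order_n=0)


class TestIntegrate:
    def test_noise_free_exponential_decay(self):
        # dI = -0.5 I dt from I(0)=1: I(2) = e^-1, relative error O(dt)
        dt = 1e-3
        cfg = SimulationConfig(dt=dt, n_steps=2000, initial_value=1.0, seed=0)
        ens = integrate(ControlPolynomial(lambda0=0.5), StableLaw(1.5, 0.0), cfg)
        assert ens.values[-1, 0] == pytest.approx(np.exp(-1.0), rel=5 * dt)

    def test_matches_hand_rolled_reference(self):
        # 10 steps, one lane: the integrator must equal a literal Euler loop
        # fed the same noise stream, to machine precision
        alpha, scale, lam0, lam2, dt, seed = 1.5, 0.7, 0.2, 0.5, 0.01, 123
        cfg = SimulationConfig(dt=dt, n_steps=10, n_realizations=1, seed=seed)
        ens = integrate(
            ControlPolynomial(lambda0=lam0, lambda2n=lam2, order_n=1),
            StableLaw(alpha, scale),
            cfg,
        )
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        z = _cms_unit(alpha, (10, 1), rng)[:, 0]
        I, ref = 0.0, []
        for k in range(10):
            I = I + (-(lam0 * I + lam2 * I**3)) * dt + scale * dt ** (1 / alpha) * z[k]
            ref.append(I)
        np.testing.assert_array_equal(ens.values[:, 0], np.array(ref))

    def test_ou_stationary_variance(self):
        # alpha = 2: Ornstein-Uhlenbeck; stationary variance sigma2/lambda0
        lam0, scale = 1.0, 1.0
        cfg = SimulationConfig(
            dt=0.01, n_steps=220_000, burn_in=20_000, n_realizations=8,
            seed=7, record_stride=10,
        )
        ens = integrate(ControlPolynomial(lambda0=lam0), StableLaw(2.0, scale), cfg)
        x = ens.pooled()
        sigma2 = scale**2  # scale**alpha at alpha=2
        assert x.var() == pytest.approx(sigma2 / lam0, rel=0.05)

    def test_stationary_law_is_stable(self):
        # lambda0 > 0, no nonlinearity: stationary law is stable with width
        # sigma_alpha^2(inf) = sigma2/(lambda0*alpha), i.e. scale = width^(1/alpha)
        alpha, lam0 = 1.5, 0.5
        cfg = SimulationConfig(
            dt=0.005, n_steps=140_000, burn_in=20_000, n_realizations=8,
            seed=8, record_stride=40,
        )
        ens = integrate(ControlPolynomial(lambda0=lam0), StableLaw(alpha, 1.0), cfg)
        x = ens.pooled()
        s_stat = (1.0 / (lam0 * alpha)) ** (1.0 / alpha)
        for w in (0.3, 0.6, 1.0):
            ecf = np.mean(np.cos(w * x))
            assert ecf == pytest.approx(np.exp(-((s_stat * w) ** alpha)), abs=0.02)

    def test_distributional_symmetry(self):
        cfg = SimulationConfig(
            dt=0.01, n_steps=30_000, burn_in=5_000, n_realizations=24, seed=9,
        )
        ens = integrate(
            ControlPolynomial(lambda2n=1.0, order_n=1), StableLaw(1.5, 1.0), cfg
        )
        # correlated within a trajectory: judge the median per realization
        # against the between-realization scatter
        med = np.median(ens.values, axis=0)
        assert abs(med.mean()) < 3 * med.std(ddof=1) / np.sqrt(med.size)

    def test_dt_convergence_of_stationary_iqr(self):
        # halving dt changes the cubic-control stationary IQR by < 2%
        def iqr(dt, steps):
            cfg = SimulationConfig(
                dt=dt, n_steps=steps, burn_in=steps // 5, n_realizations=16,
                seed=11, record_stride=max(1, int(0.05 / dt)),
            )
            ens = integrate(
                ControlPolynomial(lambda2n=1.0, order_n=1), StableLaw(1.5, 1.0), cfg
            )
            x = ens.pooled()
            return np.quantile(x, 0.75) - np.quantile(x, 0.25)

        a, b = iqr(2e-3, 100_000), iqr(1e-3, 200_000)
        assert abs(a - b) / b < 0.02

    def test_overflow_guard_names_step(self):
        cfg = SimulationConfig(
            dt=0.01, n_steps=50_000, n_realizations=2, seed=3, overflow_guard=50.0,
        )
        with pytest.raises(IntegrationError, match="step"):
            integrate(ControlPolynomial(), StableLaw(1.5, 1.0), cfg)

    def test_config_contracts(self):
        with pytest.raises(ParameterError):
            SimulationConfig(dt=0.0, n_steps=10)
        with pytest.raises(ParameterError):
            SimulationConfig(dt=0.1, n_steps=10, burn_in=10)


class TestSecondMoment:
    def test_gaussian_matches_width_formula(self):
        # variance(t) = sigma2 (1 - exp(-2 lambda0 t)) / lambda0 at alpha = 2
        lam0 = 0.5
        cfg = SimulationConfig(
            dt=0.01, n_steps=800, n_realizations=4000, seed=21,
        )
        ens = integrate(ControlPolynomial(lambda0=lam0), StableLaw(2.0, 1.0), cfg)
        times = np.array([1.0, 2.0, 6.0])
        m2 = ensemble_second_moment(ens, times)
        expected = (1.0 - np.exp(-2 * lam0 * times)) / lam0
        np.testing.assert_allclose(m2, expected, rtol=0.1)

    def test_free_flight_median_growth(self):
        # n=0, lambda0=0, alpha<2: the divergent-moment regime; the median of
        # I^2 grows like t^(2/alpha) across the ensemble
        cfg = SimulationConfig(dt=0.01, n_steps=4000, n_realizations=600, seed=22)
        ens = integrate(ControlPolynomial(), StableLaw(1.5, 1.0), cfg)
        times = np.array([5.0, 10.0, 20.0, 40.0])
        med = ensemble_second_moment(ens, times, robust=True)
        assert np.all(np.diff(med) > 0)
        slope = np.polyfit(np.log(times), np.log(med), 1)[0]
        assert slope == pytest.approx(2.0 / 1.5, rel=0.2)

    def test_cubic_control_saturates(self):
        # single-time medians are noisy; average the diagnostic over a few
        # nearby time points at T and at 2T
        cfg = SimulationConfig(dt=0.01, n_steps=13_000, n_realizations=1500, seed=23)
        ens = integrate(
            ControlPolynomial(lambda2n=1.0, order_n=1), StableLaw(1.5, 1.0), cfg
        )
        t1 = 60.0
        early = t1 * np.array([0.85, 0.9, 0.95, 1.0])
        late = 2 * early
        a = ensemble_second_moment(ens, early, robust=True).mean()
        b = ensemble_second_moment(ens, late, robust=True).mean()
        assert abs(b - a) / a < 0.10

    def test_time_beyond_span_rejected(self):
        cfg = SimulationConfig(dt=0.01, n_steps=100, n_realizations=4, seed=1)
        ens = integrate(ControlPolynomial(lambda0=1.0), StableLaw(2.0, 1.0), cfg)
        with pytest.raises(DataError):
            ensemble_second_moment(ens, [5.0])
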