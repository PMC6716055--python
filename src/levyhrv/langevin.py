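"""Stochastic integration of the inter-beat-increment dynamics.

The model is the Langevin equation

    dI = -(lambda0 * I + lambda2n * I**(2n+1)) dt + d xi(t),

with ``xi`` a symmetric alpha-stable process.  The polynomial drift is the
hypothesised sinoatrial control: ``n = 0`` is plain linear negative feedback,
``n = 1`` the cubic reduction of a cooperative pacemaker network at
criticality.  The noise increment over a step ``dt`` is
``scale * dt**(1/alpha) * zeta`` with ``zeta`` a unit-scale stable draw, as
forced by the self-similarity of the stable process.

Integration is explicit Euler-Maruyama with a stiffness guard: a heavy-tailed
kick can land far up the polynomial potential where a full explicit step would
overshoot, so whenever ``|drift| * dt > 0.5 * |I| + 0.5`` the deterministic
relaxation over that step is sub-cycled with adaptively sized Euler sub-steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, IntegrationError, ParameterError
from .stable import StableLaw, _cms_unit

__all__ = [
    "ControlPolynomial",
    "SimulationConfig",
    "IncrementSeries",
    "IncrementEnsemble",
    "LangevinModel",
    "drift",
    "integrate",
    "ensemble_second_moment",
]


@dataclass(frozen=True)
class ControlPolynomial:
    """Feedback drift specification ``-lambda0*I - lambda2n*I**(2n+1)``.

    ``order_n`` is the (even-symmetry) feedback order: the gain is
    ``lambda0 + lambda2n * I**(2n)``, so the drift stays an odd function and
    the control preserves the sign symmetry of the increments.  Both
    coefficients zero is allowed (free Lévy flight).
    """

    lambda0: float = 0.0
    lambda2n: float = 0.0
    order_n: int = 0

    def __post_init__(self) -> None:
        if self.lambda0 < 0 or self.lambda2n < 0:
            raise ParameterError("feedback coefficients must be >= 0")
        if not isinstance(self.order_n, (int, np.integer)) or self.order_n < 0:
            raise ParameterError(f"order_n must be a nonnegative integer, got {self.order_n}")
        if self.order_n >= 1 and self.lambda2n <= 0:
            raise ParameterError("lambda2n must be > 0 when order_n >= 1")

    @property
    def power(self) -> int:
        """Exponent of the nonlinear drift term, ``2n + 1``."""
        return 2 * self.order_n + 1


@dataclass(frozen=True)
class SimulationConfig:
    """Plumbing for one integration run.

    ``n_steps`` is the total number of Euler steps, of which the first
    ``burn_in`` are discarded; after the burn-in every ``record_stride``-th
    state is recorded (stride > 1 decorrelates the recorded samples).
    """

    dt: float
    n_steps: int
    burn_in: int = 0
    n_realizations: int = 1
    initial_value: float = 0.0
    seed: int = 0
    record_stride: int = 1
    overflow_guard: float = 1e12

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.n_steps < 1 or self.burn_in < 0 or self.burn_in >= self.n_steps:
            raise ParameterError("need 0 <= burn_in < n_steps")
        if self.n_realizations < 1 or self.record_stride < 1:
            raise ParameterError("n_realizations and record_stride must be >= 1")

    @property
    def n_recorded(self) -> int:
        return (self.n_steps - self.burn_in) // self.record_stride


@dataclass(frozen=True)
class IncrementSeries:
    """A single recorded increment trajectory with its time step and provenance."""

    values: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise ParameterError("values must be a non-empty 1-d sequence")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")


@dataclass(frozen=True)
class IncrementEnsemble:
    """Recorded states of an ensemble of trajectories.

    ``values`` has shape ``(n_recorded, n_realizations)``; row ``k`` was
    recorded at time ``(burn_in + (k+1)*stride) * dt`` from the start.
    """

    values: np.ndarray
    dt: float
    record_stride: int
    meta: dict = field(default_factory=dict)

    @property
    def n_realizations(self) -> int:
        return self.values.shape[1]

    def pooled(self) -> np.ndarray:
        """All recorded states flattened into one sample pool."""
        return self.values.ravel()

    def series(self, j: int) -> IncrementSeries:
        return IncrementSeries(self.values[:, j], self.dt * self.record_stride, dict(self.meta))

    def to_csv(self, path) -> None:
        """Write trajectories as CSV (step, time, value per realization) with a
        JSON metadata sidecar ``<path>.meta.json``."""
        path = Path(path)
        n = self.values.shape[0]
        step = np.arange(n) * self.record_stride
        t = step * self.dt
        cols = np.column_stack([step, t, self.values])
        header = "step,time," + ",".join(f"value_{j}" for j in range(self.n_realizations))
        np.savetxt(path, cols, delimiter=",", header=header, comments="")
        meta = dict(self.meta)
        meta.update(dt=self.dt, record_stride=self.record_stride)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True, default=str)
        )


def drift(value, control: ControlPolynomial):
    """Deterministic drift ``-lambda0*v - lambda2n*v**(2n+1)`` (odd in ``v``)."""
    v = np.asarray(value, dtype=float)
    out = -(control.lambda0 * v + control.lambda2n * v ** control.power)
    return float(out) if out.shape == () else out


def _relax(y: float, span: float, lam0: float, lam2n: float, p: int) -> float:
    """Deterministic drift flow over ``span`` via adaptively sized Euler
    sub-steps (step bounded by a fifth of the local relaxation time)."""
    t = 0.0
    while t < span:
        stiff = lam0 + p * lam2n * abs(y) ** (p - 1)
        h = span - t if stiff <= 0 else min(span - t, 0.2 / stiff)
        y = y + (-(lam0 * y + lam2n * y ** p)) * h
        t += h
    return y


def integrate(
    control: ControlPolynomial, law: StableLaw, config: SimulationConfig
) -> IncrementEnsemble:
    """Euler-Maruyama integration of the controlled Lévy-driven dynamics.

    Returns the recorded post-burn-in ensemble.  A trajectory escaping beyond
    ``config.overflow_guard`` raises :class:`IntegrationError` naming the step.
    Reproducible per ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    lam0, lam2n, p = control.lambda0, control.lambda2n, control.power
    dt, stride = config.dt, config.record_stride
    n_real = config.n_realizations
    sdt = law.scale * dt ** (1.0 / law.alpha)
    I = np.full(n_real, float(config.initial_value))
    out = np.empty((config.n_recorded, n_real))
    guard = config.overflow_guard
    rec = 0
    block = 512
    k = 0
    while k < config.n_steps:
        m = min(block, config.n_steps - k)
        Z = _cms_unit(law.alpha, (m, n_real), rng) if sdt > 0 else None
        for j in range(m):
            d = -(lam0 * I + lam2n * I ** p)
            In = I + d * dt
            viol = np.abs(d) * dt > 0.5 * np.abs(I) + 0.5
            if viol.any():
                for idx in np.flatnonzero(viol):
                    In[idx] = _relax(I[idx], dt, lam0, lam2n, p)
            I = In + (sdt * Z[j] if Z is not None else 0.0)
            kk = k + j
            if not np.all(np.abs(I) < guard):
                raise IntegrationError(
                    f"trajectory overflow (|I| >= {guard:g}) at step {kk}"
                )
            if kk >= config.burn_in and (kk - config.burn_in) % stride == stride - 1:
                if rec < out.shape[0]:
                    out[rec] = I
                    rec += 1
        k += m
    meta = {
        "control": {"lambda0": lam0, "lambda2n": lam2n, "order_n": control.order_n},
        "law": {"alpha": law.alpha, "scale": law.scale},
        "seed": config.seed,
        "dt": dt,
        "n_steps": config.n_steps,
        "burn_in": config.burn_in,
        "record_stride": stride,
        "initial_value": config.initial_value,
    }
    return IncrementEnsemble(out[:rec], dt, stride, meta)


def ensemble_second_moment(
    ensemble: IncrementEnsemble, times, robust: bool = False
) -> np.ndarray:
    """Across-realization second moment of ``I`` at the requested times.

    With ``robust=True`` the median of ``I**2`` replaces the mean — the
    recommended read-out in the divergent-moment regime (``n = 0``,
    ``alpha < 2``), where the ensemble mean of an infinite moment never
    settles but the median still grows at the self-similar rate ``t**(2/alpha)``.
    """
    if ensemble.n_realizations < 2:
        raise DataError("ensemble_second_moment needs >= 2 realizations")
    dt_rec = ensemble.dt * ensemble.record_stride
    times = np.atleast_1d(np.asarray(times, dtype=float))
    idx = np.round(times / dt_rec).astype(int) - 1
    n = ensemble.values.shape[0]
    if np.any(idx < 0) or np.any(idx >= n):
        raise DataError(
            f"requested time beyond trajectory span (have {n * dt_rec:g} time units)"
        )
    sq = ensemble.values[idx] ** 2
    return np.median(sq, axis=1) if robust else np.mean(sq, axis=1)


class LangevinModel:
    """Model object binding a control polynomial to a stable noise law.

    Thin statsmodels-style front end: construct with the physical parameters,
    call :meth:`simulate` for trajectories.  Tail estimation on the simulated
    stationary pool lives in :func:`levyhrv.steady_state.fit_tail_exponent`;
    :meth:`predicted_tail_exponent` gives the theoretical target
    ``mu = alpha + 2n + 1``.
    """

    def __init__(self, control: ControlPolynomial, law: StableLaw):
        self.control = control
        self.law = law

    def simulate(self, config: SimulationConfig) -> IncrementEnsemble:
        return integrate(self.control, self.law, config)

    def predicted_tail_exponent(self) -> float:
        from .steady_state import predicted_mu

        return predicted_mu(self.law.alpha, self.control.order_n)

    def __repr__(self) -> str:  # pragma: no cover
        c, l = self.control, self.law
        return (
            f"LangevinModel(lambda0={c.lambda0}, lambda2n={c.lambda2n}, "
            f"order_n={c.order_n}, alpha={l.alpha}, scale={l.scale})"
        )
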