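"""Symmetric alpha-stable (Lévy) laws: sampling, density, and width evolution.

The whole package uses a single characteristic-function convention,

    E[exp(i w X)] = exp(-(scale**alpha) * |w|**alpha),

so that ``alpha = 2`` is Gaussian with variance ``2 * scale**2`` and
``alpha = 1`` is Cauchy with half-width ``scale``.  The coefficient that
multiplies the fractional diffusion operator in the Fokker-Planck picture
("sigma squared" in the physics literature) is ``scale**alpha`` per unit time
under this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate as _integrate

from .errors import IntegrationError, ParameterError

__all__ = [
    "StableLaw",
    "WidthParams",
    "sample_stable",
    "stable_pdf",
    "width_evolution",
]


@dataclass(frozen=True)
class StableLaw:
    """A symmetric alpha-stable law.

    Parameters
    ----------
    alpha : float
        Stability index, in (0, 2].  ``alpha = 2`` is Gaussian, ``alpha = 1``
        Cauchy; ``alpha < 2`` implies an infinite variance and a density tail
        proportional to ``|x|**-(1 + alpha)``.
    scale : float
        Dispersion parameter in the units of the variate, >= 0.  ``scale = 0``
        is accepted as a degenerate (noise-free) sentinel: all mass at zero.
    """

    alpha: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 2.0):
            raise ParameterError(f"alpha must be in (0, 2], got {self.alpha}")
        if not (self.scale >= 0.0) or not math.isfinite(self.scale):
            raise ParameterError(f"scale must be finite and >= 0, got {self.scale}")

    @property
    def noise_strength(self) -> float:
        """Coefficient of the fractional diffusion operator per unit time
        (the sigma-squared of the Fokker-Planck form): ``scale**alpha``."""
        return self.scale ** self.alpha


@dataclass(frozen=True)
class WidthParams:
    """Parameters of the time-dependent Lévy width under linear feedback.

    ``lambda0`` is the linear relaxation rate (1/time, >= 0), ``sigma2`` the
    noise strength multiplying the fractional operator, ``alpha`` the
    stability index of the driver.
    """

    lambda0: float
    sigma2: float
    alpha: float

    def __post_init__(self) -> None:
        if self.lambda0 < 0:
            raise ParameterError(f"lambda0 must be >= 0, got {self.lambda0}")
        if self.sigma2 <= 0:
            raise ParameterError(f"sigma2 must be > 0, got {self.sigma2}")
        if not (0.0 < self.alpha <= 2.0):
            raise ParameterError(f"alpha must be in (0, 2], got {self.alpha}")


def _cms_unit(alpha: float, size, rng: np.random.Generator) -> np.ndarray:
    """Unit-scale symmetric stable draws via the Chambers-Mallows-Stuck
    transform (exact for every alpha in (0, 2])."""
    u = rng.uniform(-np.pi / 2.0, np.pi / 2.0, size)
    if alpha == 1.0:
        return np.tan(u)
    w = rng.exponential(1.0, size)
    t1 = np.sin(alpha * u) / np.cos(u) ** (1.0 / alpha)
    t2 = (np.cos(u - alpha * u) / w) ** ((1.0 - alpha) / alpha)
    return t1 * t2


def sample_stable(law: StableLaw, count: int, seed=None) -> np.ndarray:
    """Draw ``count`` i.i.d. variates from ``law``.

    ``seed`` may be an integer, a ``SeedSequence`` or a ``Generator``;
    draws are reproducible for a fixed seed.
    """
    if count < 1:
        raise ParameterError(f"count must be >= 1, got {count}")
    rng = np.random.default_rng(seed)
    if law.scale == 0.0:
        return np.zeros(count)
    return law.scale * _cms_unit(law.alpha, count, rng)


def _pdf_scalar(x: float, alpha: float, scale: float) -> float:
    # Fourier-cosine inversion of the characteristic function.  The integrand
    # cos(x w) exp(-(scale w)^alpha) is smooth and exponentially damped; cut
    # the domain where the envelope falls below 1e-12 and let the oscillatory
    # quadrature rule handle the cosine factor.
    omega_max = (12.0 * math.log(10.0)) ** (1.0 / alpha) / scale
    envelope = lambda w: math.exp(-((scale * w) ** alpha))
    if x == 0.0:
        val, err = _integrate.quad(envelope, 0.0, omega_max, limit=200)
    else:
        val, err = _integrate.quad(
            envelope, 0.0, omega_max, weight="cos", wvar=x, limit=200
        )
    if err > 1e-7 + 1e-3 * abs(val):
        raise IntegrationError(
            f"stable_pdf quadrature did not converge at x={x}: "
            f"value={val:.3e}, error estimate={err:.3e}"
        )
    return max(val / math.pi, 0.0)


def stable_pdf(value, law: StableLaw):
    """Probability density of ``law`` at ``value`` (scalar or array).

    Evaluates ``(1/pi) * Int_0^inf cos(value*w) exp(-(scale*w)**alpha) dw``
    by adaptive quadrature.  Symmetric in ``value`` and normalised to one
    within quadrature tolerance.
    """
    if law.scale == 0.0:
        raise ParameterError("stable_pdf undefined for the degenerate scale=0 law")
    vals = np.asarray(value, dtype=float)
    out = np.array(
        [_pdf_scalar(abs(float(x)), law.alpha, law.scale) for x in vals.ravel()]
    )
    out = out.reshape(vals.shape)
    return float(out) if np.isscalar(value) or vals.shape == () else out


def width_evolution(t, params: WidthParams):
    """Time-dependent Lévy width ``sigma_alpha^2(t)`` under linear feedback.

    Returns ``sigma2 * (1 - exp(-alpha*lambda0*t)) / (lambda0*alpha)`` for
    ``lambda0 > 0`` and the removable limit ``sigma2 * t`` at ``lambda0 = 0``.
    Strictly increasing in ``t``; for ``lambda0 > 0`` bounded above by the
    stationary width ``sigma2 / (lambda0 * alpha)``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    if params.lambda0 == 0.0:
        out = params.sigma2 * t
    else:
        a_l = params.alpha * params.lambda0
        out = params.sigma2 * (-np.expm1(-a_l * t)) / a_l
    return float(out) if out.shape == () else out
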