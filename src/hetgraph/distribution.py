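"""Modified two-parameter Weibull distribution in the sigma parameterization.

The ordinary Weibull density with shape ``alpha > 0`` and scale ``lam > 0``
is

    f(x; lam, alpha) = (alpha/lam) (x/lam)^(alpha-1) exp(-(x/lam)^alpha).

Mapping the shape parameter through ``sigma = exp(-alpha)`` compresses the
whole shape range onto the unit interval, giving the modified density

    f(x; lam, sigma) = (-ln sigma / lam) (x/lam)^(-ln sigma - 1)
                       exp(-(x/lam)^(-ln sigma)),   sigma in (0, 1).

``sigma`` acts as a heterogeneity dial for degree distributions: sigma -> 0
(alpha -> infinity) concentrates all mass at ``lam`` (regular graphs), while
sigma -> 1 (alpha -> 0) produces heavy, subexponential tails.  Intermediate
special cases: sigma = e^-1 is the exponential distribution, sigma = e^-2
the Rayleigh, and sigma = e^-3.4 is approximately Gaussian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "HeterogeneityParams",
    "sigma_from_alpha",
    "alpha_from_sigma",
    "pdf",
    "cdf",
    "sample",
    "mean_degree",
    "variance_degree",
    "second_moment_degree",
]


def sigma_from_alpha(alpha: float) -> float:
    """Map a Weibull shape parameter to the heterogeneity scale.

    Parameters
    ----------
    alpha : float
        Weibull shape parameter; must be strictly positive and finite.

    Returns
    -------
    float
        ``exp(-alpha)``, strictly inside (0, 1).
    """
    if not math.isfinite(alpha) or alpha <= 0:
        raise ValueError(
            f"alpha must be a finite positive real (shape parameter), got {alpha!r}"
        )
    return math.exp(-alpha)


def alpha_from_sigma(sigma: float) -> float:
    """Invert the heterogeneity mapping: ``alpha = -ln(sigma)``.

    ``sigma`` must lie strictly inside (0, 1); the boundary values correspond
    to degenerate (alpha = infinity) and scale-free-limit (alpha = 0) cases
    that the parameterization excludes.
    """
    if not (isinstance(sigma, (int, float)) and math.isfinite(sigma)) or not (
        0.0 < sigma < 1.0
    ):
        raise ValueError(
            f"sigma must lie strictly in the open interval (0, 1), got {sigma!r}"
        )
    return -math.log(sigma)


@dataclass(frozen=True)
class HeterogeneityParams:
    """The (sigma, lam) pair defining a modified Weibull degree distribution.

    Attributes
    ----------
    sigma : float
        Heterogeneity level, strictly in (0, 1).  Dimensionless.
    lam : float
        Scale parameter, strictly positive; the value the degree
        distribution is centered at (units of degree).
    alpha : float
        Derived Weibull shape parameter ``-ln(sigma)``; always finite and
        positive for valid instances.
    """

    sigma: float
    lam: float
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        alpha = alpha_from_sigma(self.sigma)  # validates sigma
        if not (isinstance(self.lam, (int, float)) and math.isfinite(self.lam)) or (
            self.lam <= 0
        ):
            raise ValueError(f"lam must be a finite positive real, got {self.lam!r}")
        object.__setattr__(self, "lam", float(self.lam))
        object.__setattr__(self, "sigma", float(self.sigma))
        object.__setattr__(self, "alpha", alpha)

    @classmethod
    def from_alpha(cls, alpha: float, lam: float) -> "HeterogeneityParams":
        """Construct from the conventional Weibull shape parameter."""
        return cls(sigma=sigma_from_alpha(alpha), lam=lam)


def pdf(params: HeterogeneityParams, x) -> np.ndarray | float:
    """Density of the modified Weibull distribution.

    Evaluates ``(-ln s/lam) (x/lam)^(-ln s - 1) exp(-(x/lam)^(-ln s))``
    elementwise.  At ``x = 0`` the formula's own limit is returned: 0 for
    alpha > 1, ``1/lam`` for alpha = 1 (exponential case), and IEEE ``inf``
    for alpha < 1, where the density genuinely diverges at the origin.

    Parameters
    ----------
    params : HeterogeneityParams
    x : array_like of float, >= 0

    Returns
    -------
    float or ndarray
        Density value(s), non-negative (possibly ``inf`` at 0 for alpha < 1).
    """
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("pdf is defined on x >= 0 only")
    a, lam = params.alpha, params.lam
    with np.errstate(divide="ignore", over="ignore"):
        z = xa / lam
        out = (a / lam) * z ** (a - 1.0) * np.exp(-(z**a))
    # 0^(a-1) is inf for a < 1 and numpy emits nan for inf*0 chains; fix up
    if np.any(xa == 0):
        if a < 1.0:
            boundary = np.inf
        elif a == 1.0:
            boundary = 1.0 / lam
        else:
            boundary = 0.0
        out = np.where(xa == 0, boundary, out)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def cdf(params: HeterogeneityParams, x) -> np.ndarray | float:
    """Closed-form CDF ``1 - exp(-(x/lam)^alpha)`` with ``alpha = -ln sigma``."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValueError("cdf is defined on x >= 0 only")
    out = 1.0 - np.exp(-((xa / params.lam) ** params.alpha))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def sample(
    params: HeterogeneityParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw i.i.d. samples by exact inverse-transform sampling.

    Uses ``x = lam * (-ln u)^(1/alpha)`` with ``u`` uniform on the open
    interval (0, 1), so a draw is never exactly zero and the empirical CDF
    converges to :func:`cdf` (a clean Kolmogorov-Smirnov oracle).

    Parameters
    ----------
    params : HeterogeneityParams
    n : int
        Number of draws, >= 1.
    rng : numpy.random.Generator
        Seeded generator; identical state gives identical output.

    Returns
    -------
    ndarray of shape (n,)
        Non-negative samples.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    u = rng.random(int(n))
    # rng.random() returns values in [0, 1); reflect to (0, 1] so that
    # log never sees an exact zero argument
    u = 1.0 - u
    return params.lam * (-np.log(u)) ** (1.0 / params.alpha)


def mean_degree(params: HeterogeneityParams) -> float:
    """Analytic mean ``lam * Gamma(1 - 1/ln sigma) = lam * Gamma(1 + 1/alpha)``."""
    return params.lam * float(_gamma(1.0 + 1.0 / params.alpha))


def variance_degree(params: HeterogeneityParams) -> float:
    """Analytic variance ``lam^2 [Gamma(1 + 2/alpha) - Gamma(1 + 1/alpha)^2]``."""
    a = params.alpha
    g1 = float(_gamma(1.0 + 1.0 / a))
    g2 = float(_gamma(1.0 + 2.0 / a))
    return params.lam**2 * (g2 - g1**2)


def second_moment_degree(params: HeterogeneityParams) -> float:
    """Raw second moment ``E[k^2] = lam^2 * Gamma(1 + 2/alpha)``.

    Exposed alongside :func:`variance_degree` because mean-field spectral
    formulas are conventionally written in terms of the raw second moment
    ``<k^2>`` rather than the variance.
    """
    return params.lam**2 * float(_gamma(1.0 + 2.0 / params.alpha))
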