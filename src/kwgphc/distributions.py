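"""Kumaraswamy distribution primitives and competitor families.

The Kumaraswamy distribution ``K(alpha, beta)`` lives on the unit interval
with cdf ``F(x) = 1 - (1 - x**alpha)**beta`` and density
``f(x) = alpha*beta*x**(alpha-1)*(1-x**alpha)**(beta-1)``.  Both shape
parameters are positive.  Because the cdf, quantile function and survival
(reliability) function are all in closed form it is a convenient substitute
for the beta distribution when modelling bounded data such as scaled
reservoir capacities, rainfall fractions or test scores.

Two competitor families used for goodness-of-fit comparison are exposed
through :func:`competitor_cdf_pdf`: the exponentiated exponential
distribution (EED, ``F = (1 - exp(-beta*x))**alpha``) and the Lomax
distribution (``F = 1 - (1 + x/beta)**(-alpha)``).  Both are evaluated via
the corresponding :mod:`scipy.stats` frozen distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "KumaraswamyParams",
    "CompetitorParams",
    "kw_cdf",
    "kw_pdf",
    "kw_logpdf",
    "kw_quantile",
    "kw_reliability",
    "kw_rvs",
    "competitor_frozen",
    "competitor_cdf_pdf",
]


@dataclass(frozen=True)
class KumaraswamyParams:
    """Positive shape-parameter pair of a Kumaraswamy distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"shape parameters must be positive, got alpha={self.alpha}, beta={self.beta}"
            )

    def as_tuple(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


@dataclass(frozen=True)
class CompetitorParams:
    """Parameters of a goodness-of-fit competitor family (``EED`` or ``Lomax``)."""

    family: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.family not in ("EED", "Lomax"):
            raise ValueError(f"unknown family {self.family!r}; expected 'EED' or 'Lomax'")
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("competitor parameters must be positive")


def _check_shapes(alpha: float, beta: float) -> None:
    if not (np.all(np.asarray(alpha) > 0) and np.all(np.asarray(beta) > 0)):
        raise ValueError("Kumaraswamy shape parameters must be positive")


def _log_surv_kernel(x, alpha):
    """log(1 - x**alpha), evaluated in log space for x close to 1."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    xa = np.zeros_like(x)  # x**alpha, with the x=0 limit filled in directly
    pos = x > 0
    xa[pos] = np.exp(alpha * np.log(x[pos]))
    with np.errstate(divide="ignore"):
        return np.log1p(-xa)


def kw_cdf(x, alpha: float, beta: float):
    """Cumulative distribution function of ``K(alpha, beta)``.

    Raises ``ValueError`` outside ``[0, 1]`` or for nonpositive shapes.
    """
    _check_shapes(alpha, beta)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("Kumaraswamy support is the unit interval [0, 1]")
    scalar = x.ndim == 0
    out = -np.expm1(beta * _log_surv_kernel(x, alpha))
    out = np.where(np.atleast_1d(x) >= 1.0, 1.0, out)
    return float(out[0]) if scalar else out


def kw_logpdf(x, alpha: float, beta: float):
    _check_shapes(alpha, beta)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("log-density requires x strictly inside (0, 1)")
    lx = np.log(x)
    out = np.log(alpha * beta) + (alpha - 1.0) * lx + (beta - 1.0) * np.log1p(-np.exp(alpha * lx))
    return out if out.ndim else float(out)


def kw_pdf(x, alpha: float, beta: float):
    """Density of ``K(alpha, beta)``.

    At the exact endpoints the limiting value is returned (``0``, a finite
    constant, or ``inf`` depending on the shape regime) instead of raising,
    so the function can be used directly for plotting and quadrature.
    """
    _check_shapes(alpha, beta)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("Kumaraswamy support is the unit interval [0, 1]")
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    interior = (x > 0) & (x < 1)
    out[interior] = np.exp(kw_logpdf(x[interior], alpha, beta))
    # endpoint limits of alpha*beta*x^(a-1)*(1-x^a)^(b-1)
    at0 = x == 0.0
    out[at0] = 0.0 if alpha > 1 else (beta if alpha == 1 else np.inf)
    at1 = x == 1.0
    out[at1] = 0.0 if beta > 1 else (alpha if beta == 1 else np.inf)
    return float(out[0]) if scalar else out


def kw_quantile(u, alpha: float, beta: float):
    """Inverse cdf: ``(1 - (1-u)**(1/beta))**(1/alpha)``, with stable log forms."""
    _check_shapes(alpha, beta)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = -np.expm1(np.log1p(-u) / beta)  # 1 - (1-u)^(1/beta), stable for tiny u
        out = np.exp(np.log(inner) / alpha)
    out = np.where(u >= 1.0, 1.0, np.where(u <= 0.0, 0.0, out))
    return out if out.ndim else float(out)


def kw_reliability(t, alpha: float, beta: float):
    """Survival probability ``R(t) = (1 - t**alpha)**beta``; 0 for ``t >= 1``."""
    _check_shapes(alpha, beta)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("mission time must be nonnegative")
    scalar = t.ndim == 0
    inside = np.clip(t, 0.0, 1.0)
    out = np.exp(beta * _log_surv_kernel(inside, alpha))
    out = np.where(np.atleast_1d(t) >= 1.0, 0.0, out)
    return float(out[0]) if scalar else out


def kw_rvs(alpha: float, beta: float, size=None, rng=None):
    """Random variates by inversion of the closed-form quantile function."""
    rng = np.random.default_rng(rng)
    return kw_quantile(rng.random(size), alpha, beta)


def competitor_frozen(params: CompetitorParams):
    """Frozen scipy distribution for a competitor family.

    EED is the exponentiated exponential ``F = (1-exp(-beta*x))**alpha``,
    i.e. ``scipy.stats.exponweib`` with Weibull exponent 1 and scale
    ``1/beta``.  Lomax uses the standard survival exponent ``-alpha``
    (``scipy.stats.lomax`` with scale ``beta``).
    """
    if params.family == "EED":
        return stats.exponweib(a=params.alpha, c=1.0, scale=1.0 / params.beta)
    return stats.lomax(c=params.alpha, scale=params.beta)


def competitor_cdf_pdf(x, params: CompetitorParams):
    """Return ``(cdf, pdf)`` of a competitor family at ``x > 0``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("competitor families are supported on x > 0")
    frozen = competitor_frozen(params)
    cdf, pdf = frozen.cdf(x), frozen.pdf(x)
    if x.ndim == 0:
        return float(cdf), float(pdf)
    return cdf, pdf
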