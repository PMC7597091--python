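"""Ground-truth posterior expectations by deterministic 2-D quadrature.

This module exists to validate the Lindley and Tierney–Kadane
approximations: it evaluates the ratio of posterior integrals directly on a
tensor-product Gauss–Legendre grid over ``(alpha, beta)``, in the log domain
with a single max-shift.  The integration box is centered on the joint
posterior mode with Wald-style spreads taken from the curvature there
(priors may be improper, so the box cannot be prior-driven) and is widened
and refined until the estimate stabilizes.  It is intentionally simple and
slow; it is not part of the estimation surface.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize

from .model import KumaraswamyGPHC
from .priors import GammaPrior

__all__ = [
    "posterior_expectation",
    "conditional_beta_shape_rate",
    "conditional_beta_quad_mean",
]


def _log_posterior_grid(model: KumaraswamyGPHC, prior: GammaPrior, A, B):
    """Vectorized log posterior kernel on meshgrid arrays A, B."""
    x = model.sample.x
    w = model._w
    D = model.D
    lx = np.log(x)
    xa = np.exp(A[..., None] * lx)  # broadcast over the grid
    log_surv = np.log1p(-xa)
    E0 = np.zeros_like(A)
    if model._is_case2:
        T, Rs = model.sample.T, model.sample.Rstar_next
        E0 = Rs * np.log1p(-T**A)
    ll = (
        D * np.log(A * B)
        + (A - 1.0) * lx.sum()
        + B * (log_surv @ w + E0)
        - log_surv.sum(axis=-1)
    )
    return ll + prior.log_kernel(A, B)


def _posterior_mode(model, prior):
    start = model.fit().params

    def neg(th):
        a, b = th
        if a <= 0 or b <= 0:
            return np.inf
        return -(model.loglike(th) + float(prior.log_kernel(a, b)))

    res = minimize(neg, start, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    mode = res.x
    # Wald spreads from the likelihood curvature at the mode
    H = model.hessian(mode) + prior.log_kernel_hess(*mode)
    cov = np.linalg.inv(-H)
    sd = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
    return mode, sd


#: refinement ladder of (box half-width in Wald sds, nodes per axis); the
#: box widens faster than the node count grows because the residual error is
#: dominated by tail truncation, not by the Gauss rule.
_LADDER = ((10.0, 160), (20.0, 240), (40.0, 480), (80.0, 720), (120.0, 960))


def posterior_expectation(
    model: KumaraswamyGPHC,
    prior: GammaPrior,
    g: Callable[[np.ndarray, np.ndarray], np.ndarray],
    rtol: float = 1e-6,
) -> float:
    """Posterior expectation ``E[g(alpha, beta) | data]`` by quadrature.

    ``g`` must accept meshgrid arrays.  The grid is refined (box widened,
    nodes increased) until successive estimates agree to ``rtol``; failure
    to converge raises ``RuntimeError``.
    """
    mode, sd = _posterior_mode(model, prior)
    previous = None
    for w, N in _LADDER:
        lo = np.maximum(mode - w * sd, 1e-8)
        hi = mode + w * sd
        za, wa = leggauss(N)
        zb, wb = leggauss(N)
        A1 = (za + 1.0) / 2.0 * (hi[0] - lo[0]) + lo[0]
        B1 = (zb + 1.0) / 2.0 * (hi[1] - lo[1]) + lo[1]
        A, B = np.meshgrid(A1, B1, indexing="ij")
        lp = _log_posterior_grid(model, prior, A, B)
        lp -= lp.max()
        W = np.outer(wa, wb) * np.exp(lp)
        denom = W.sum()
        estimate = float(np.sum(W * g(A, B)) / denom)
        if previous is not None and abs(estimate - previous) <= rtol * max(1.0, abs(previous)):
            return estimate
        previous = estimate
    raise RuntimeError("posterior quadrature did not converge under refinement")


# ---------------------------------------------------------------------------
# conjugate reduction: with alpha held fixed the posterior of beta is gamma
# ---------------------------------------------------------------------------

def conditional_beta_shape_rate(
    model: KumaraswamyGPHC, prior: GammaPrior, alpha: float
) -> tuple[float, float]:
    """Shape and rate of the conditional posterior ``beta | alpha, data``.

    The likelihood is gamma-shaped in ``beta``:
    ``beta**D * exp(beta * S)`` with
    ``S = sum((1+R)*log(1-x**alpha)) + E(alpha) < 0``, so with the gamma
    prior the conditional posterior is ``Gamma(D + c, d - S)``.
    """
    S = float(np.dot(model._w, model._log_surv(alpha)) + model.e_terms(alpha)[0])
    return model.D + prior.c, prior.d - S


def conditional_beta_quad_mean(
    model: KumaraswamyGPHC, prior: GammaPrior, alpha: float, nodes: int = 400
) -> float:
    """1-D quadrature mean of ``beta | alpha, data`` (checks the closed form)."""
    shape, rate = conditional_beta_shape_rate(model, prior, alpha)
    mode = max(shape - 1.0, 1.0) / rate
    sd = np.sqrt(shape) / rate
    lo, hi = max(1e-10, mode - 12 * sd), mode + 12 * sd
    z, w = leggauss(nodes)
    b = (z + 1.0) / 2.0 * (hi - lo) + lo
    logk = (shape - 1.0) * np.log(b) - rate * b
    logk -= logk.max()
    kern = w * np.exp(logk)
    return float(np.sum(kern * b) / np.sum(kern))
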