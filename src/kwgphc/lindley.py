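"""Lindley's two-parameter expansion for posterior expectations.

For a posterior proportional to ``exp(l + kappa)`` (log-likelihood plus log
prior kernel) the posterior mean of a smooth function ``g(alpha, beta)`` is
approximated, to second order around the MLE, by

    E[g] ~= g + 0.5*[A + l03*B21 + l30*B12 + l12*C21 + l21*C12]
            + kappa_1*A12 + kappa_2*A21,

with ``tau`` the inverse of the negative Hessian of ``l``, ``l_ij`` the third
partials, ``kappa_i`` the prior-score components, and the aggregates

    A    = sum_ij w_ij tau_ij,
    A_ij = w_i tau_ii + w_j tau_ji,
    B_ij = (w_i tau_ii + w_j tau_ij) * tau_ii,
    C_ij = 3 w_i tau_ii tau_ij + w_j (tau_ii tau_jj + 2 tau_ij**2),

where ``w_i``/``w_ij`` are the partials of ``g``.  For this model
``l12 = 0`` identically, since the likelihood is linear in ``beta`` apart
from the ``D*log(beta)`` term.

Loss functions enter only through ``g``: squared error uses the target
itself, linex uses ``exp(-p*theta)`` followed by ``-(1/p)*log``, and general
entropy uses ``theta**(-q)`` followed by ``**(-1/q)``.  The derivative sets
are produced by the chain rule from the raw target derivatives, so a single
evaluation routine covers all nine (loss, target) combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import KumaraswamyGPHC
from .priors import GammaPrior, LossSpec

__all__ = ["LindleyComponents", "lindley_components", "lindley_estimate", "target_derivatives"]


@dataclass(frozen=True)
class LindleyComponents:
    """Likelihood curvature pieces evaluated at the MLE."""

    G: float  # -l_aa
    H: float  # -l_bb  ( = D / beta**2 )
    I: float  # -l_ab
    M: float  # G*H - I**2
    tau11: float
    tau22: float
    tau12: float
    l30: float
    l21: float
    l12: float  # identically zero; kept for completeness
    l03: float
    kappa1: float
    kappa2: float


def lindley_components(
    model: KumaraswamyGPHC, mle_params, prior: GammaPrior
) -> LindleyComponents:
    """Evaluate curvature, third derivatives and prior scores at the MLE."""
    alpha, beta = float(mle_params[0]), float(mle_params[1])
    hess = model.hessian([alpha, beta])
    G, H, I = -hess[0, 0], -hess[1, 1], -hess[0, 1]
    M = G * H - I * I
    if M <= 0:
        raise ValueError("singular information matrix: likelihood is flat at the MLE")

    lx = model._logx
    xa = np.exp(alpha * lx)
    om = 1.0 - xa
    w = model._w
    _, _, E2, E3 = model.e_terms(alpha)
    D = model.D
    third = lx**3 * xa * (1.0 + xa) / om**3
    l30 = float(2.0 * D / alpha**3 + beta * (-np.dot(w, third) + E3) + third.sum())
    l21 = float(-np.dot(w, lx**2 * xa / om**2) + E2)
    l03 = 2.0 * D / beta**3
    kappa = prior.log_kernel_grad(alpha, beta)
    return LindleyComponents(
        G=float(G), H=float(H), I=float(I), M=float(M),
        tau11=float(H / M), tau22=float(G / M), tau12=float(-I / M),
        l30=l30, l21=l21, l12=0.0, l03=float(l03),
        kappa1=float(kappa[0]), kappa2=float(kappa[1]),
    )


def target_derivatives(target: str, alpha: float, beta: float, t: float | None):
    """Value and partials (w1, w2, w11, w12, w22) of the raw target.

    Targets are ``alpha``, ``beta`` and ``reliability`` (the survival
    probability ``R(t) = (1 - t**alpha)**beta`` at mission time ``t``).
    """
    if target == "alpha":
        return dict(g=alpha, w1=1.0, w2=0.0, w11=0.0, w12=0.0, w22=0.0)
    if target == "beta":
        return dict(g=beta, w1=0.0, w2=1.0, w11=0.0, w12=0.0, w22=0.0)
    if target == "reliability":
        if t is None or not (0.0 < t < 1.0):
            raise ValueError("reliability target needs a mission time t in (0, 1)")
        lt = np.log(t)
        ta = t**alpha
        ls = np.log1p(-ta)  # log(1 - t**alpha)
        R = np.exp(beta * ls)
        return dict(
            g=R,
            w1=-beta * ta * lt * np.exp((beta - 1.0) * ls),
            w2=R * ls,
            w11=beta * ta * lt**2 * np.exp((beta - 2.0) * ls) * (beta * ta - 1.0),
            w12=-ta * lt * np.exp((beta - 1.0) * ls) * (1.0 + beta * ls),
            w22=R * ls**2,
        )
    raise ValueError(f"unknown target {target!r}")


def _loss_transform(base: dict, loss: LossSpec) -> dict:
    """Chain rule from the raw target theta to g = exp(-p*theta) (linex) or
    g = theta**(-q) (entropy)."""
    if loss.kind == "SEL":
        return base
    g0, w1, w2 = base["g"], base["w1"], base["w2"]
    w11, w12, w22 = base["w11"], base["w12"], base["w22"]
    if loss.kind == "LL":
        p = loss.p
        f = np.exp(-p * g0)
        return dict(
            g=f,
            w1=-p * f * w1,
            w2=-p * f * w2,
            w11=f * (p * p * w1 * w1 - p * w11),
            w12=f * (p * p * w1 * w2 - p * w12),
            w22=f * (p * p * w2 * w2 - p * w22),
        )
    q = loss.q
    if g0 <= 0:
        raise ValueError("entropy loss requires a positive target value")
    f = g0 ** (-q)
    f1 = -q * g0 ** (-q - 1.0)
    f2 = q * (q + 1.0) * g0 ** (-q - 2.0)
    return dict(
        g=f,
        w1=f1 * w1,
        w2=f1 * w2,
        w11=f2 * w1 * w1 + f1 * w11,
        w12=f2 * w1 * w2 + f1 * w12,
        w22=f2 * w2 * w2 + f1 * w22,
    )


def lindley_estimate(
    model: KumaraswamyGPHC,
    mle_params,
    prior: GammaPrior,
    target: str,
    loss: LossSpec,
    t: float | None = None,
    components: LindleyComponents | None = None,
    clamp_reliability: bool = False,
) -> float:
    """Lindley approximate-Bayes estimate of a target under a loss.

    Out-of-range reliability estimates are reported raw with a warning; set
    ``clamp_reliability=True`` to clip them into ``[0, 1]`` instead.  A
    nonpositive bracket under the linex or entropy transform (an expansion
    failure, seen only on very small samples) raises ``ValueError``.
    """
    c = components or lindley_components(model, mle_params, prior)
    alpha, beta = float(mle_params[0]), float(mle_params[1])
    d = _loss_transform(target_derivatives(target, alpha, beta, t), loss)
    w1, w2 = d["w1"], d["w2"]
    t11, t22, t12 = c.tau11, c.tau22, c.tau12
    A = d["w11"] * t11 + 2.0 * d["w12"] * t12 + d["w22"] * t22
    A12 = w1 * t11 + w2 * t12
    A21 = w2 * t22 + w1 * t12
    B12 = (w1 * t11 + w2 * t12) * t11
    B21 = (w2 * t22 + w1 * t12) * t22
    C12 = 3.0 * w1 * t11 * t12 + w2 * (t11 * t22 + 2.0 * t12**2)
    C21 = 3.0 * w2 * t22 * t12 + w1 * (t22 * t11 + 2.0 * t12**2)
    ghat = (
        d["g"]
        + 0.5 * (A + c.l03 * B21 + c.l30 * B12 + c.l12 * C21 + c.l21 * C12)
        + c.kappa1 * A12
        + c.kappa2 * A21
    )
    if loss.kind == "SEL":
        est = float(ghat)
    elif loss.kind == "LL":
        if ghat <= 0:
            raise ValueError("linex expansion produced a nonpositive bracket")
        est = float(-np.log(ghat) / loss.p)
    else:
        if ghat <= 0:
            raise ValueError("entropy expansion produced a nonpositive bracket")
        est = float(ghat ** (-1.0 / loss.q))
    if target == "reliability" and not (0.0 <= est <= 1.0):
        if clamp_reliability:
            est = float(np.clip(est, 0.0, 1.0))
        else:
            warnings.warn(
                f"Lindley reliability estimate {est:.4f} outside [0, 1]; reported raw",
                RuntimeWarning,
            )
    return est
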