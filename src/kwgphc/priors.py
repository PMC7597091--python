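"""Gamma priors and loss specifications for the Bayes estimators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GammaPrior", "LossSpec"]


@dataclass(frozen=True)
class GammaPrior:
    """Independent gamma priors on the two shape parameters.

    The prior kernel is ``alpha**(a-1) * beta**(c-1) * exp(-b*alpha - d*beta)``
    (normalizing constants are irrelevant to every posterior ratio computed
    here).  The convention ``a = b = c = d = 0`` is the noninformative prior,
    with kernel ``1/(alpha*beta)``; it is improper but yields a proper
    posterior whenever at least one failure is observed.
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("gamma hyperparameters must be nonnegative")

    @classmethod
    def noninformative(cls) -> "GammaPrior":
        return cls(0.0, 0.0, 0.0, 0.0)

    def log_kernel(self, alpha, beta):
        """log prior kernel, up to an additive constant."""
        return (
            (self.a - 1.0) * np.log(alpha)
            - self.b * alpha
            + (self.c - 1.0) * np.log(beta)
            - self.d * beta
        )

    def log_kernel_grad(self, alpha, beta):
        return np.array(
            [(self.a - 1.0) / alpha - self.b, (self.c - 1.0) / beta - self.d]
        )

    def log_kernel_hess(self, alpha, beta):
        return np.diag([-(self.a - 1.0) / alpha**2, -(self.c - 1.0) / beta**2])


@dataclass(frozen=True)
class LossSpec:
    """Loss function under which a Bayes estimate is taken.

    ``SEL`` is squared error (posterior mean).  ``LL`` is the linex loss with
    asymmetry ``p != 0``: the estimator is ``-(1/p) * log E[exp(-p*theta)]``,
    penalizing overestimation more heavily for ``p > 0``.  ``EL`` is the
    general entropy loss with exponent ``q != 0``: the estimator is
    ``E[theta**(-q)]**(-1/q)``, penalizing positive errors more for ``q > 0``.
    """

    kind: str = "SEL"
    p: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("SEL", "LL", "EL"):
            raise ValueError(f"loss kind must be SEL, LL or EL, got {self.kind!r}")
        if self.kind == "LL" and (self.p is None or self.p == 0):
            raise ValueError("linex loss requires a nonzero asymmetry p")
        if self.kind == "EL" and (self.q is None or self.q == 0):
            raise ValueError("entropy loss requires a nonzero exponent q")

    @classmethod
    def parse(cls, text: str) -> "LossSpec":
        """Parse ``'sel'``, ``'linex:0.2'`` or ``'entropy:0.8'``."""
        head, _, arg = text.lower().partition(":")
        if head == "sel":
            return cls("SEL")
        if head == "linex":
            return cls("LL", p=float(arg))
        if head == "entropy":
            return cls("EL", q=float(arg))
        raise ValueError(f"unknown loss specification {text!r}")

    @property
    def label(self) -> str:
        if self.kind == "SEL":
            return "SEL"
        if self.kind == "LL":
            return f"LL(p={self.p:g})"
        return f"EL(q={self.q:g})"
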