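"""Censoring designs, progressive Type-II generation and GPHC truncation.

A progressively Type-II censored life test starts with ``n`` units; at the
``j``-th observed failure ``R_j`` surviving units are withdrawn, until ``m``
failures have been seen.  The *generalized progressive hybrid* variant (GPHC)
additionally fixes a threshold time ``T`` and a minimum acceptable number of
failures ``k <= m``, and stops at ``T* = max(min(T, X_m), X_k)``.  Three
outcomes are possible:

* Case I  (``T < X_k``): the test runs past ``T`` until the ``k``-th failure;
  the first ``k`` failures are observed.
* Case II (``X_k < T < X_m``): the test stops at ``T`` with ``J`` failures
  observed (``X_J < T < X_{J+1}``) and the remaining units removed at ``T``.
* Case III (``X_m < T``): all ``m`` planned failures are observed.

Generation follows the Balakrishnan–Sandhu uniform transform: with iid
standard uniforms ``W_i`` set ``Z_i = W_i**(1/(i + R_m + ... + R_{m-i+1}))``,
``Y_i = 1 - Z_m * ... * Z_{m-i+1}``, then map through the inverse cdf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .distributions import KumaraswamyParams, kw_quantile

__all__ = [
    "CensoringScheme",
    "GPHCSample",
    "generate_progressive_type2",
    "classify_and_truncate",
    "effective_removals",
    "generate_gphc_sample",
]


@dataclass(frozen=True)
class CensoringScheme:
    """Planned GPHC design ``(n, m, k, T, R)``.

    ``R`` is the vector of planned removals at each of the ``m`` failures and
    must satisfy ``sum(R) + m == n``.  ``k`` is the minimum acceptable number
    of failures, ``T`` the threshold time (inside ``(0, 1)`` for lifetimes on
    the unit interval).
    """

    n: int
    m: int
    k: int
    T: float
    R: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", tuple(int(r) for r in self.R))
        if not (1 <= self.m <= self.n):
            raise ValueError(f"need 1 <= m <= n, got m={self.m}, n={self.n}")
        if not (1 <= self.k <= self.m):
            raise ValueError(f"need 1 <= k <= m, got k={self.k}, m={self.m}")
        if self.T <= 0:
            raise ValueError("threshold time T must be positive")
        if len(self.R) != self.m:
            raise ValueError(f"removal vector has length {len(self.R)}, expected m={self.m}")
        if any(r < 0 for r in self.R):
            raise ValueError("removals must be nonnegative")
        if sum(self.R) + self.m != self.n:
            raise ValueError(
                f"inconsistent scheme: sum(R) + m = {sum(self.R) + self.m} != n = {self.n}"
            )

    # -- named removal patterns used throughout the Monte-Carlo study --------
    @classmethod
    def pattern(cls, name: str, n: int, m: int, k: int, T: float) -> "CensoringScheme":
        """Named removal patterns: ``scheme_I`` removes all n-m at the first
        failure, ``scheme_II`` at the last, ``scheme_III`` splits between the
        two ends (first gets the extra unit when n-m is odd)."""
        nm = n - m
        name = name.lower().removeprefix("scheme_")
        if name == "i":
            R = (nm,) + (0,) * (m - 1)
        elif name == "ii":
            R = (0,) * (m - 1) + (nm,)
        elif name == "iii":
            first = (nm + 1) // 2
            R = (first,) + (0,) * (m - 2) + (nm - first,)
        else:
            raise ValueError(f"unknown pattern {name!r}")
        return cls(n=n, m=m, k=k, T=T, R=R)

    @classmethod
    def from_config(cls, cfg: dict) -> "CensoringScheme":
        """Build from a parsed YAML/JSON mapping.

        ``R`` may be an explicit list or one of the named patterns
        ``scheme_I`` / ``scheme_II`` / ``scheme_III``.
        """
        R = cfg["R"]
        if isinstance(R, str):
            return cls.pattern(R, n=cfg["n"], m=cfg["m"], k=cfg["k"], T=cfg["T"])
        return cls(n=cfg["n"], m=cfg["m"], k=cfg["k"], T=cfg["T"], R=tuple(R))

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "m": self.m, "k": self.k, "T": self.T, "R": list(self.R)})


@dataclass(frozen=True)
class GPHCSample:
    """A realized GPHC sample.

    ``Reff`` holds the effective removal count attached to each observed
    failure; ``Rstar_next`` is the terminal removal applied at time ``T`` in
    Case II (zero otherwise).  With the pooled terminal-removal convention
    the accounting identity ``D + sum(Reff) + Rstar_next == n`` holds; a
    sample constructed with explicit removals may deliberately leave units
    unaccounted (see :func:`classify_and_truncate`), which is permitted but
    flagged by :attr:`is_balanced`.
    """

    case: str
    x: np.ndarray
    Reff: np.ndarray
    Rstar_next: int
    scheme: CensoringScheme

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        Reff = np.asarray(self.Reff, dtype=int)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "Reff", Reff)
        if self.case not in ("I", "II", "III"):
            raise ValueError(f"case must be one of I/II/III, got {self.case!r}")
        if x.size == 0:
            raise ValueError("a GPHC sample must contain at least one failure")
        if np.any(np.diff(x) <= 0):
            raise ValueError("failure times must be strictly increasing")
        if np.any((x <= 0) | (x >= 1)):
            raise ValueError("failure times must lie strictly inside (0, 1)")
        if Reff.size != x.size:
            raise ValueError("Reff must have one entry per observed failure")
        if np.any(Reff < 0) or self.Rstar_next < 0:
            raise ValueError("negative removal count signals an inconsistent scheme")
        if self.D + int(Reff.sum()) + self.Rstar_next > self.scheme.n:
            raise ValueError("removals account for more units than the design contains")

    @property
    def D(self) -> int:
        return int(self.x.size)

    @property
    def T(self) -> float:
        return self.scheme.T

    @property
    def n(self) -> int:
        return self.scheme.n

    @property
    def is_balanced(self) -> bool:
        """True when every one of the n units is accounted for."""
        return self.D + int(self.Reff.sum()) + self.Rstar_next == self.scheme.n


def effective_removals(
    scheme: CensoringScheme, case: str, D: int
) -> tuple[np.ndarray, int]:
    """Effective removal counts ``(Reff, Rstar_next)`` for a given case.

    Case I pools every unit still on test at the ``k``-th failure into the
    terminal removal ``R_k* = n - k - sum(R_i, i<k)``; Case II removes
    ``R_{J+1}* = n - J - sum(R_i, i<=J)`` at ``T``; Case III uses the planned
    vector unchanged.
    """
    R = np.asarray(scheme.R, dtype=int)
    if case == "I":
        if D != scheme.k:
            raise ValueError("Case I observes exactly k failures")
        terminal = scheme.n - scheme.k - int(R[: scheme.k - 1].sum())
        if terminal < 0:
            raise ValueError("negative terminal removal: inconsistent scheme")
        Reff = np.concatenate([R[: scheme.k - 1], [terminal]])
        return Reff, 0
    if case == "II":
        if not (scheme.k <= D < scheme.m):
            raise ValueError("Case II requires k <= J < m observed failures")
        rstar = scheme.n - D - int(R[:D].sum())
        if rstar < 0:
            raise ValueError("negative terminal removal: inconsistent scheme")
        return R[:D].copy(), int(rstar)
    if case == "III":
        if D != scheme.m:
            raise ValueError("Case III observes all m failures")
        return R.copy(), 0
    raise ValueError(f"unknown case {case!r}")


def classify_and_truncate(
    full_sample, scheme: CensoringScheme, case_i_terminal: str = "pooled"
) -> GPHCSample:
    """Truncate a full progressive Type-II sample into a GPHC sample.

    ``full_sample`` must be the sorted vector of all ``m`` failure times.
    Ties with ``T`` (possible with rounded data) are classified as failures
    observed before ``T``.

    ``case_i_terminal`` controls the Case I terminal removal: ``"pooled"``
    (default) uses the count ``R_k* = n - k - sum(R_i, i<k)`` so that every
    unit is accounted for; ``"planned"`` keeps the scheme's ``R_k`` as the
    final removal, a convention encountered in published analyses in which
    the units beyond ``R_k`` simply drop out of the likelihood.
    """
    x = np.asarray(full_sample, dtype=float)
    if x.size != scheme.m:
        raise ValueError(f"expected the full m={scheme.m} failures, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("full sample must be sorted strictly increasing")
    if case_i_terminal not in ("pooled", "planned"):
        raise ValueError("case_i_terminal must be 'pooled' or 'planned'")

    J = int(np.sum(x <= scheme.T))  # failures observed by T (ties count as observed)
    if J < scheme.k:
        # Case I: run past T to the k-th failure
        if case_i_terminal == "pooled":
            Reff, rstar = effective_removals(scheme, "I", scheme.k)
        else:
            Reff, rstar = np.asarray(scheme.R[: scheme.k], dtype=int), 0
        return GPHCSample(case="I", x=x[: scheme.k], Reff=Reff, Rstar_next=rstar, scheme=scheme)
    if J >= scheme.m:
        Reff, rstar = effective_removals(scheme, "III", scheme.m)
        return GPHCSample(case="III", x=x, Reff=Reff, Rstar_next=rstar, scheme=scheme)
    Reff, rstar = effective_removals(scheme, "II", J)
    return GPHCSample(case="II", x=x[:J], Reff=Reff, Rstar_next=rstar, scheme=scheme)


def generate_progressive_type2(
    scheme: CensoringScheme, params: KumaraswamyParams | tuple[float, float], rng=None
) -> np.ndarray:
    """Generate the full ``m`` progressively censored Kumaraswamy failures.

    Uses the Balakrishnan–Sandhu inverse transform: the uniforms ``W`` are
    drawn in a single batch of ``m`` so that a fixed seed reproduces the
    sample exactly.
    """
    if not isinstance(params, KumaraswamyParams):
        params = KumaraswamyParams(*params)
    rng = np.random.default_rng(rng)
    m = scheme.m
    R = np.asarray(scheme.R, dtype=float)
    W = rng.random(m)
    # exponent denominators: i + R_m + R_{m-1} + ... + R_{m-i+1}
    tail_sums = np.concatenate([[0.0], np.cumsum(R[::-1])])[1:]
    denom = np.arange(1, m + 1) + tail_sums
    Z = W ** (1.0 / denom)
    # Y_i = 1 - Z_m Z_{m-1} ... Z_{m-i+1}
    Y = 1.0 - np.cumprod(Z[::-1])
    return kw_quantile(Y, params.alpha, params.beta)


def generate_gphc_sample(
    scheme: CensoringScheme,
    params: KumaraswamyParams | tuple[float, float],
    rng=None,
    case_i_terminal: str = "pooled",
) -> GPHCSample:
    """Draw a full progressive Type-II sample and truncate it to GPHC form."""
    full = generate_progressive_type2(scheme, params, rng=rng)
    return classify_and_truncate(full, scheme, case_i_terminal=case_i_terminal)
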