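# Methods

This note records the model conventions, numerical choices and known
limitations of `kwgphc`, in the spirit of a statistical package's methods
appendix.  Everything quantitative below is computed by the test suite or
by `scripts/acceptance.py`; nothing is asserted that the code does not
verify.

## Model and likelihood

Lifetimes are Kumaraswamy `K(α, β)` on the unit interval, cdf
`F(x) = 1 − (1 − x^α)^β`.  A GPHC sample consists of the ordered observed
failures `x_1 < … < x_D`, the effective removal counts `R_j` attached to
each failure, and (Case II only) a terminal removal `R*` applied at the
threshold time `T`.  The combined log-likelihood over the three censoring
cases, dropping parameter-free ordering constants, is

    l(α, β) = D log(αβ) + (α−1) Σ log x_j
              + β [ Σ (1+R_j) log(1 − x_j^α) + E(α) ] − Σ log(1 − x_j^α),

with `E(α) = R* log(1 − T^α)` in Case II and zero otherwise.  Note that the
whole survival bundle — including `E(α)` — is multiplied by β: each
censored unit contributes `(1 − x^α)^β` to the likelihood.  All
`log(1 − x^α)` terms are evaluated as `log1p(-exp(α log x))` to avoid
cancellation as lifetimes approach 1.

### Case conventions

* **Case II sample size.**  `J` counts every failure at or below `T`
  (a tie `x_j = T`, possible with rounded data, counts as observed); the
  terminal removal is `R*_{J+1} = n − J − Σ_{i≤J} R_i`.  For the packaged
  reservoir subsample with `T = 0.75` this gives `J = 18`
  (`x_18 = 0.744881 < 0.75 < x_19 = 0.767135`) and `R* = 6`.
* **Case I terminal removal.**  When the test runs past `T` to the `k`-th
  failure, every unit still on test is withdrawn there, so the default
  ("pooled") convention sets the last effective removal to
  `R_k* = n − k − Σ_{i<k} R_i`, preserving the accounting identity
  `D + Σ R_eff + R* = n`.  A second convention ("planned") keeps the
  scheme's `R_k` as the final removal and lets the remaining survivors
  drop out of the likelihood entirely; it appears in published analyses of
  this dataset and is what the packaged Case I fixture uses
  (`n=42, k=19`: planned removal 1 versus pooled count 5).  Both are
  exposed via `classify_and_truncate(..., case_i_terminal=...)`.

## Maximum likelihood

β is profiled out in closed form; the α-score along the profile is solved
by the fixed-point iteration `α ← g(α)` with start `α₀ = 1`, stopping rule
`|Δα| < 1e-8` and a 500-iteration cap.  The raw iteration can oscillate, so
a detected sign flip in successive steps switches to half-damped updates,
and any failure (non-convergence, nonpositive iterate, or a residual score
above 1e-6) falls back to a bracketed `brentq` solve of the profiled score
on an expanding interval.  Every fit is verified to satisfy the score
equations; the fixed-point and bracketed routes agree to 1e-7 relative on
the packaged data, and to 1e-4 against a 2-D grid-plus-polish search on
small simulated samples.

Reliability is reported by invariance, `R̂(t) = (1 − t^α̂)^β̂`, with the
evaluation time defaulting to the design threshold `T` — the convention
that back-solves the published real-data table for all three cases.

## Priors, losses and approximate Bayes

Independent gamma priors `π(α, β) ∝ α^{a−1} β^{c−1} e^{−bα−dβ}`; all four
hyperparameters zero is the noninformative convention `1/(αβ)` (improper,
but the posterior is proper whenever at least one failure is observed).
Three losses are supported: squared error (SEL; the posterior mean), linex
with asymmetry `p ≠ 0` (estimator `−(1/p) log E[e^{−pθ}]`; `p > 0` punishes
overestimation), and general entropy with exponent `q ≠ 0` (estimator
`E[θ^{−q}]^{−1/q}`; positive errors weigh more when `q > 0`, and `q = −1`
recovers the posterior mean exactly).

**Lindley.**  The two-parameter second-order expansion around the MLE is
implemented once, in its general form (curvature inverse `τ`, third
partials `l30, l21, l12 ≡ 0, l03`, prior scores `κ`), with the target- and
loss-specific derivative sets produced by the chain rule from the raw
targets `α`, `β`, `R(t)`.  This single routine reproduces the nine
hand-written closed forms to machine precision and keeps each derivative
individually finite-difference tested.

**Tierney–Kadane.**  The posterior expectation of a positive `g` is a
ratio of two Laplace approximations with exponents
`δ = (l + log π)/n` and `δ* = δ + log g / n`.  Both maximizations use
analytic gradients and Hessians (L-BFGS-B, started at the MLE and at the
δ-maximizer respectively).  The determinant ratio enters through its
square root — the variant that tracks exact quadrature posterior means;
formulations that print the unrooted ratio are reachable through the
`determinant_power` option but are not the default, as they are far less
accurate (3.56 versus the exact 3.20 on the packaged Case I fixture).  The
divisor `n` cancels algebraically; tests verify invariance to replacing it
by `D`.

**Accuracy (as measured by the quadrature oracle).**  TK posterior means
are second-order accurate: worst error 0.4% on n=15 complete samples and
0.2% on the real-data fixtures.  Lindley is comparable on the real-data
fixtures (0.1–0.5%) but degrades sharply on small samples whose MLE
conflicts with an informative prior — median ~5% with a heavy tail at
n=15 — because the prior enters only through a linear correction term.
The linex route deserves a caveat: TK applied to `g = e^{−pθ}` carries a
first-order (O(1/D)) error rather than the second-order error of the SEL
and entropy routes, so the `p → 0` limit of the TK linex estimate
approaches the TK SEL estimate only to within a few percent on samples of
this size (the limit itself exists and is stable).  For Lindley the
`p → 0` limit recovers SEL exactly.  Reliability estimates from either
expansion can leave [0, 1] on extreme samples; they are reported raw with
a warning (clamping is opt-in) so that users see the expansion failure.

## Quadrature oracle

`kwgphc.oracle.posterior_expectation` evaluates posterior ratios on a
tensor Gauss–Legendre grid in the log domain with a single max-shift.  The
box is centered on the joint posterior mode with Wald spreads from the
curvature there (priors may be improper, so bounds cannot come from the
prior) and follows a refinement ladder that widens the box faster than it
adds nodes — the residual error is tail truncation, not rule error.  The
last two rungs agree to 1e-7 relative on the packaged fixtures.  With α
held fixed the posterior of β is conjugate, `Gamma(D + c, d − S)` with
`S = Σ (1+R_j) log(1 − x_j^α) + E(α)`; this closed form, its 1-D
quadrature, and a closed-form 1-D TK reduction cross-check the 2-D
machinery to 1e-3 relative or better.

## Synthetic data and the Monte-Carlo study

Progressive Type-II uniform samples are generated by the standard inverse
transform (powers of batch-drawn uniforms, cumulative products, then the
Kumaraswamy quantile function), and truncated into GPHC form.  The study
defaults are the reference conditions: truth `(α, β) = (3, 2)`, threshold
`T = 0.9`, removal patterns I (all removals at the first failure), II (all
at the last) and III (split between the ends), linex `p ∈ {0.2, 0.8}`,
entropy `q ∈ {0.2, 0.8}`, a noninformative prior and the informative prior
`(a, b, c, d) = (1.5, 0.5, 1, 0.5)` whose means equal the truth.  The
reference replication count is 1000; the package default is S = 200, which
resolves the qualitative orderings (MSE falling with n, with m at fixed n,
and with k at fixed n and m, within twice the Monte-Carlo standard error)
at a few seconds per design.  Replicates where an estimator fails (for
example a nonpositive linex bracket on a tiny sample) are dropped from
that estimator's moments with a reported count.

What the generator does *not* emulate: real storage fractions are
seasonally autocorrelated and rounded; the simulator draws iid lifetimes.
Passing distributional tests therefore validates the censoring mechanics
and estimator calibration, not the adequacy of the iid Kumaraswamy model
for any particular hydrological series.

## Goodness of fit

Complete-data ML fits of Kumaraswamy, exponentiated exponential
(`F = (1−e^{−βx})^α`) and Lomax families, compared by AIC, AICc, BIC and
Kolmogorov–Smirnov.  The Lomax cdf uses the valid negative survival
exponent `1 − (1 + x/β)^{−α}`; on the packaged reservoir data its
likelihood is maximized in the boundary limit `α, β → ∞` (an exponential
law), which the optimizer reports as very large parameters with the
correct limiting likelihood.  Two K–S variants are provided: the standard
one-sample sup-distance with the asymptotic Kolmogorov p-value
(informational only, since parameters are estimated), and a two-sample
comparison against one random equal-size draw from the fitted model —
a convention found in published tables for this dataset, whose statistic
is a multiple of `1/n` and explicitly stochastic.  The one-sample form is
the recommended summary.

## Known limitations

* Quantile/cdf round-tripping saturates in double precision once
  `F(x)` is within ~1e-16 of 0 or 1; no inverse can recover `x` there.
* No standard errors or credible intervals are produced; the focus is
  point estimation under the three losses.
* The Lindley expansion is unreliable for strongly informative priors on
  samples with fewer than ~30 failures (see the accuracy paragraph); use
  TK or the quadrature oracle in that regime.
* `k = m` is permitted (Cases I and III then coincide at the `k`-th
  failure); `k > m` and non-integer removals are rejected.
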