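# kwgphc

Estimation for Kumaraswamy lifetimes under **generalized progressive hybrid
censoring** (GPHC): a censored-sample simulator, maximum-likelihood fitting
via a profile/fixed-point scheme, approximate-Bayes estimators (Lindley and
Tierney–Kadane) under symmetric and asymmetric losses, a Monte-Carlo
evaluation driver, and complete-data goodness-of-fit comparison.

## The problem

Life tests are rarely run to completion.  In a *progressively Type-II
censored* test, `n` units start on test and a planned number `R_j` of
survivors is withdrawn at the `j`-th observed failure, until `m` failures
are seen.  The *generalized progressive hybrid* scheme additionally fixes a
threshold time `T` and a minimum acceptable failure count `k ≤ m`, stopping
at `T* = max(min(T, X_m), X_k)`.  Three outcomes result:

* **Case I** (`T < X_k`): run past `T` until the `k`-th failure;
* **Case II** (`X_k < T < X_m`): stop at `T` with `J` failures observed and
  a terminal removal `R*_{J+1} = n − J − ΣR_i`;
* **Case III** (`X_m < T`): all `m` planned failures observed.

Lifetimes are modelled by the Kumaraswamy distribution `K(α, β)` on (0, 1),

```
F(x) = 1 − (1 − x^α)^β,   f(x) = αβ x^{α−1} (1 − x^α)^{β−1},   α, β > 0,
```

a closed-form alternative to the beta distribution, well suited to bounded
hydrological data (storage fractions, rainfall proportions).  The quantity
of applied interest is the reliability `R(t) = (1 − t^α)^β`.

## Estimators

**Maximum likelihood.**  Up to constants the GPHC log-likelihood is

```
l(α, β) = D log(αβ) + (α−1) Σ log x_j
          + β [ Σ (1+R_j) log(1 − x_j^α) + E(α) ] − Σ log(1 − x_j^α),
```

with `D` the observed failure count and `E(α) = R* log(1 − T^α)` the Case II
censoring term (zero otherwise).  β profiles out exactly,
`β̂(α) = −D / [Σ (1+R_j) log(1 − x_j^α) + E(α)]`, and α solves a fixed-point
equation `α = g(α)` iterated from `α₀ = 1` with damping and a bracketed
root-solve safeguard.

**Bayes.**  Independent gamma priors on α and β (hyperparameters
`a, b, c, d`; all zero is the noninformative convention) and three losses:
squared error (posterior mean), linex with asymmetry `p`, and general
entropy with exponent `q`.  The posterior ratios have no closed form and are
approximated two ways: **Lindley's** second-order expansion around the MLE
(using third log-likelihood derivatives) and the **Tierney–Kadane** Laplace
ratio (separate maximization of the posterior and target-weighted posterior
exponents).  A deterministic 2-D quadrature oracle (`kwgphc.oracle`)
computes exact posterior expectations for validation.

## Worked example

The packaged dataset holds 42 monthly storage fractions of the Shasta
reservoir and a progressively censored 21-value subsample (`m = 21`, one
unit withdrawn at each failure).  Fitting the Case III design
(`T = 0.9, k = 14`):

```python
from kwgphc import KumaraswamyGPHC, GammaPrior
from kwgphc.datasets import shasta_gphc_sample

model = KumaraswamyGPHC(shasta_gphc_sample("III"))
res = model.fit()
print(res.summary())
```

```
Kumaraswamy GPHC maximum-likelihood fit
==============================================
Censoring case:        III
Units on test (n):     42
Observed failures (D): 21
Threshold time (T):    0.9
----------------------------------------------
alpha (shape):         3.145601
beta  (shape):         1.706267
R(T) plug-in:          0.115408
----------------------------------------------
log-likelihood:        -7.765066
converged:             True  (iterations=12, max|score|=8.48e-10)
```

The two shape estimates say the storage fraction is unimodal with most mass
in the middle of the unit interval, and the plug-in reliability estimates
an 11.5% chance that a month's storage exceeds 90% of capacity.  The
approximate-Bayes table under the noninformative prior:

```python
print(res.bayes_table(GammaPrior.noninformative()).round(4).to_string(index=False))
```

```
     target  method    MLE    SEL  LL(p=0.2)  LL(p=0.8)  EL(q=0.2)  EL(q=0.8)
      alpha lindley 3.1456 3.0929     3.0409     2.9051     2.9960     2.9522
      alpha      tk 3.1456 3.0969     3.0344     2.8879     2.9921     2.9379
       beta lindley 1.7063 1.7248     1.6816     1.5607     1.5788     1.5177
       beta      tk 1.7063 1.7254     1.6439     1.5391     1.5757     1.5051
reliability lindley 0.1154 0.1369     0.1365     0.1352     0.1129     0.1024
reliability      tk 0.1154 0.1381     0.1345     0.1330     0.1147     0.1017
```

Larger loss asymmetries (`p`, `q` toward 0.8) guard harder against
overestimation and pull the estimates down.

A command-line interface mirrors the library:

```bash
kwgphc fit --data shasta_censored \
  --scheme '{"n":42,"m":21,"k":14,"T":0.9,"R":"scheme_III"}'
kwgphc gof --data shasta_full
kwgphc mc-study --config study.yaml --out results.csv
```

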