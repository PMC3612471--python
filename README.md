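# bjel — empirical likelihood for right-censored linear regression

`bjel` makes inferences about the slope vector **β** of the semiparametric
linear (accelerated failure time) model

    Y_i = X_i'β + ε_i,        Z_i = min(Y_i, C_i),  δ_i = I[Y_i ≤ C_i],

from right-censored data, for analysts who want confidence intervals and
tests for covariate effects on (transformed) survival times without
assuming an error distribution, a proportional-hazards structure, or a
variance formula for the point estimator.  The error distribution F is
completely unspecified and absorbs the intercept; only slopes are
estimated.

The core construction is an empirical likelihood (EL) on the Buckley-James
estimating function.  Censored responses are imputed by their conditional
expectation under the Kaplan-Meier estimate F̂β of the residual
distribution,

    W_i(β) = (X_i − X̄) [ δ_i e_i + (1 − δ_i) E_{F̂β}(e | e > e_i) ],
    e_i = Z_i − X_i'β,

and Owen's EL ratio l_n(β₀) for "mean of W is zero" is formed.  Because
the plug-in F̂β makes the W_i dependent, l_n is not asymptotically χ²; the
calibrated statistic multiplies by a trace ratio

    c_n(β) = tr(Σ̂₂^{-1} S_n) / tr(Σ̂₁^{-1} S_n),

where Σ̂₁ is the naive second moment of the W_i, Σ̂₂ a martingale-style
variance estimator built from risk-set covariances at event residuals, and
S_n the rank-one outer product of the summed scores.  Then
c_n(β₀) l_n(β₀) → χ²_p at the true slope, tests and confidence regions
{β : c_n(β) l_n(β) ≤ χ²_{p,α}} follow with no variance estimation for the
slope estimator itself, and the region's shape is driven entirely by the
data.  Extensions included:

* **auxiliary information** — known covariate moments E g(X) = 0 enter as
  extra EL constraints, giving a χ²_{p+r} calibrated test;
* **synthetic-data baseline** — the classical
  Koul–Susarla–Van Ryzin / synthetic-variable EL
  (Yg_i = δ_i Z_i / Ĝ(Z_i−)), for comparison and as a foil: it fails when
  censoring depends on covariates;
* **simulation harness** — the five data-generating models (A–E) of the
  coverage study, censoring-rate calibration, and a reproducible
  Monte-Carlo coverage/width experiment.

## Worked example

Simulated data with one covariate, ~30% censoring, true slope 1
(`bjel.generate` model A, n = 120, written to `example.csv` with columns
`logtime,status,x`):

```
$ bjel fit example.csv --response logtime --status status --covariates x
{
  "beta_hat": [0.8371023732668914],
  "iterations": 12,
  "converged": true,
  "cycle": false,
  "ksv_beta_hat": [0.8023280466789868],
  "n": 120,
  "n_events": 86
}
```

The Buckley-James iteration converged in 12 steps to β̂ = 0.837; the
synthetic-data (KSV) slope agrees here because censoring is independent of
the covariate.  Testing the true value β₀ = 1:

```
$ bjel test example.csv --response logtime --status status --covariates x --beta0 1.0
{
  "statistic": 1.2846864383708132,
  "cn": 6.3171076265355905,
  "ln": 0.2033662420083473,
  "df": 1,
  "p_value": 0.2570294864529407,
  "status": "interior"
}
```

The raw EL ratio (0.203) is far from χ² scale; the calibration factor
c_n = 6.32 corrects it, and the adjusted statistic 1.28 (p = 0.26) does not
reject the truth.  Intervals by test inversion:

```
$ bjel ci example.csv --response logtime --status status --covariates x --level 0.95
{"lower": 0.5489616261068336, "upper": 1.12344383929416, ...}
$ bjel ci ... --method elsd --seed 7
{"lower": 0.2219026596116492, "upper": 1.5623935759117928, ...}
```

Both 95% intervals cover the true slope 1; the estimating-equation interval
(width 0.57) is less than half the width of the synthetic-data interval
(width 1.34) — the efficiency gap the coverage study quantifies.  The same
analyses run on user-supplied survival tables (e.g. transplant-registry
style data, regressing `log10` survival days on a patient covariate via
`--transform log10`); `bjel test --aux constraints.json` adds known-moment
constraints, and `bjel simulate --model A --n 100 --cr 0.3 --reps 1000`
tabulates coverage for one design cell.

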