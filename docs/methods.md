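# Methods

## Data-generating mechanism

Each repetition of a scenario simulates one balanced two-arm trial. A
latent continuous score is drawn per subject from `Normal(mu, sigma^2)`
with defaults `mu = 50`, `sigma = 22` (score points on the 0–100 PRO
scale, chosen to match a typical SF-36 bodily-pain control-group
distribution). The treatment arm receives a pure location shift
`effect_x`; the built-in effect grid {0, 4.4, 11, 17.6, 22} corresponds
to Cohen's d of {0, 0.2, 0.5, 0.8, 1.0} at sigma = 22. Latent values are
clamped to [0, 100] and then discretised onto a k-level grid.

The three built-in grids reproduce the SF-36 dimension scales:

| label | k  | scores | interior edges |
|-------|----|--------|----------------|
| RE4   | 4  | 0, 33.3, 66.6, 100 | 16.65, 49.95, 83.25 |
| BP10  | 10 | 0, 11.1, …, 88.9, 100 | 5.55, 16.65, …, 94.35 |
| MH26  | 26 | 0, 4, 8, …, 100 | 2, 6, …, 98 |

Discretisation uses left-open/right-closed bins `(edge[j-1], edge[j]]`:
a value exactly on an edge maps to the **lower** score, matching the
instrument's printed scoring intervals. The BP10 scores are the
instrument's printed values, which are not all arithmetic midpoints
(55.6 and 66.7). Generic `k` produces equally spaced scores
`100·j/(k−1)` with midpoint edges. Clamping before discretisation is
mathematically redundant (the outer bins extend to ±∞) but is kept so
the clamped continuous scores are reportable per subject.

Discretisation is idempotent and monotone; for MH26 the rounding error
of any value is at most half the 4-point bin width.

### Random-number streams

One root seed. The base latent sample for a repetition is drawn from
`default_rng([seed, n, rep_index])` — a stream keyed by the seed, the
total sample size and the repetition only. Consequences:

* **Common random numbers**: all effect sizes and all grids reuse
  bit-identical base samples (the shift is added post hoc, the grid is
  applied post hoc), so method contrasts across grids/effects are not
  diluted by sampling noise, and control-arm summaries coincide across
  effect sizes.
* Different sample sizes use independent substreams (not nested
  subsets); nesting across n was an open design choice and independence
  is the simplest reproducible contract.
* Results are bit-for-bit identical across reruns and independent of
  scenario execution order, so scenario-parallel and serial runs agree.

## Estimators

All three models regress the observed discrete score on an intercept and
the treatment indicator only (an unadjusted RCT analysis).

**MLR.** The coefficient on the indicator is the difference in arm
means; it is computed in closed form together with the pooled-variance
two-sample SE, and CI/p from the t distribution on n−2 df. This is
algebraically identical to OLS on the two-column design (verified
against statsmodels OLS in the tests). Zero within-arm variance in both
arms leaves the SE undefined; such fits are flagged non-converged.

**Tobit.** Two-sided censored-normal likelihood: scores strictly inside
(0, 100) contribute `log φ((y−η)/σ) − log σ`; scores exactly at the
lower/upper bound contribute `log Φ((a−η)/σ)` / `log(1−Φ((b−η)/σ))`.
Censoring status is assigned by exact equality with the bounds, which is
well-defined because observed scores are grid values. Interior discrete
scores are treated as exact continuous observations — the model the
estimator assumes, deliberately misspecified relative to the DGM's
discretisation, which is precisely the behaviour under study (on coarse
grids the Tobit systematically overshoots large effects).

Numerics: parameters `(β0, β1, log σ)` (log parameterisation keeps σ
positive and the problem well-scaled); start at the OLS solution with
the n-divisor residual SD (floored at 0.01 to survive degenerate
starts); BFGS with analytic gradient, gradient tolerance 1e−8, max 200
iterations. A fit is accepted when the final gradient inf-norm is below
1e−4 relative to the objective magnitude. The likelihood is evaluated on
per-arm (value, count) compressions — observed scores take at most k
distinct values, which makes 5000-repetition scenarios cheap. SEs come
from the inverse observed information, computed by central finite
differences of the analytic score (step 1e−5·(1+|θ|)) with a Cholesky
positive-definiteness check; Wald CI and p use normal quantiles
(standard MLE asymptotics; the t/z distinction is negligible at n ≥
100). All-censored samples, optimiser failure and non-PD information are
flagged non-converged. The implementation is cross-checked in the test
suite against R `survival::survreg` (gaussian, interval2 censoring) to
~1e−5 and against a grid-search maximiser.

**Median.** LAD regression via statsmodels `QuantReg` (smoothed IRLS) at
q = 0.5, with the iid-error kernel-sparsity covariance (Epanechnikov
kernel, Hall–Sheather bandwidth) — the default of Stata's `qreg`, the
software family this class of analyses is usually run in — and t-based
CI/p. Iteration-limit or cycling warnings, non-finite estimates and
non-positive sparsity estimates are flagged non-converged (observed
missing rates are ~0.1% on the 4-level grid, zero elsewhere).

Tie-break convention: with even arm sizes and heavily tied discrete
scores the LAD minimiser for an arm median is an *interval* of optimal
solutions. A simplex solver stops at a data-dependent vertex; the
smoothed IRLS used here typically settles at a vertex but can land in
the interior of the flat set. Mean estimates agree with vertex solvers
to well within Monte Carlo error, but tail behaviour under the null
(how often the fitted difference is exactly zero) differs slightly
between conventions, so null rejection rates on the coarsest grid are
convention-sensitive at the few-percent level. The convention is
recorded here; the group-median oracle tests use odd arm sizes, where
the median is unique.

## Performance measures

For a scenario's `nsim` repetitions, with non-converged fits excluded
listwise (`n_valid` in every denominator, missing count reported):

* bias `δ = mean(x̂) − x`; empirical SE (n−1 divisor); MSE (1/n divisor,
  so MSE = bias² + (n−1)/n·EmpSE² holds exactly);
* coverage = fraction of closed CIs containing x; rejection rate =
  fraction with p ≤ α (inclusive), read as Type I error when x = 0 and
  power otherwise; α defaults to 0.05, two-sided throughout;
* Monte Carlo SEs: `EmpSE/√n` (bias), `EmpSE/√(2(n−1))` (EmpSE),
  `√(r(1−r)/n)` (coverage and rejection). At nominal coverage and
  nsim = 5000 the coverage MCSE is ≈ 0.003, giving the 0.944–0.956
  acceptance band for nominal behaviour.

Performance is always assessed against the *latent* truth `x`, although
clamping plus discretisation make the observable group difference
slightly smaller than `x` for non-zero effects (for example, the
expected discretised difference at x = 22 on BP10 is ≈ 21.0). Part of
the reported "bias" is therefore a discretisation artefact by
construction; it is the estimand the study design targets, since the
latent effect is the quantity a trialist would want to recover. Only
under the null (x = 0) is the truth exactly observable.

## What the generator does and does not emulate

It reproduces: bounded, equally spaced discrete scoring; floor/ceiling
pile-up induced by clamping a latent normal; balanced randomisation; a
pure location-shift effect with equal arm variances. It does not
emulate: item-level questionnaire responses, skewed latent
distributions, variance changes under treatment, covariates, missing
data, clustering or repeated measures. Passing tests therefore
demonstrate estimator behaviour under the latent-normal location-shift
model, not under arbitrary real-world PRO distributions — a latent
normal plausibly favours the mean-based estimators.

## Problem sizes

The default study is 90 scenarios × 5000 repetitions × 3 methods (a few
hours on one CPU; the per-arm value-count compression makes Tobit ~4 ms
and QuantReg ~17 ms per fit at n = 400). The test suite runs a handful
of single scenarios at the full 5000 repetitions — enough for every
tabulated comparison at its 3×MCSE tolerance — and the acceptance
script recomputes each headline quantity the same way in a few minutes.

## Known limitations

* Median-regression tie-breaking is solver-specific (above); exact
  replication of another solver's null rejection curve on the 4-level
  grid is not expected beyond the few-percent level.
* Tobit SEs rely on a finite-difference observed information; in
  near-degenerate samples (almost everything censored) the Cholesky
  check rejects the fit rather than reporting an unstable SE.
* The CI-coverage identity between the z-based Tobit interval and its
  test (reject ⇔ truth outside CI) holds only under the null.
* Sample sizes must be even (balanced arms by construction); unbalanced
  designs are out of scope.
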