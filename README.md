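# prosim

A Monte Carlo simulation framework for comparing statistical methods
that estimate treatment effects on **bounded, discrete patient-reported
outcome (PRO) scores** in balanced two-arm randomised controlled trials.

Patient-reported outcomes such as the SF-36 dimension scores live on a
0–100 scale but can only take a small number of equally spaced discrete
values (4, 10 or 26 levels depending on the dimension), and they pile up
at the floor and ceiling. If the score is viewed as a discretised,
clamped measurement of an underlying continuous latent variable, which
regression model should a trial statistician fit? `prosim` simulates
that situation end-to-end and measures how three candidate estimators
behave, for biostatisticians planning PRO analyses and for teaching
simulation-study design.

## The model

Each simulated trial draws a latent score per subject,

```
Y*_i = mu + x * arm_i + eps_i,        eps_i ~ Normal(0, sigma^2)
```

with `mu = 50`, `sigma = 22` and a pure location-shift treatment effect
`x ∈ {0, 4.4, 11, 17.6, 22}` (Cohen's d of 0–1.0). The observed score is
`Y_i = D(clamp(Y*_i, 0, 100))`, where `D` snaps the value onto a k-level
grid (k = 4, 10 or 26) via left-open/right-closed bins. Three estimators
of `x` are fit to each of `nsim = 5000` repetitions per scenario:

* **MLR** — linear regression on the treatment indicator; the estimate
  is the difference in arm means, inference by the pooled two-sample t.
* **Tobit** — censored-normal maximum likelihood treating scores at 0
  and 100 as censored (`Y = a` if `Y* ≤ a`, `Y = b` if `Y* ≥ b`),
  estimating the latent-scale mean difference; Wald z inference from the
  observed information.
* **Median** — least-absolute-deviations (quantile) regression at
  q = 0.5, estimating the difference in conditional medians; SEs from
  the kernel-sparsity asymptotics with Hall–Sheather bandwidth.

Performance per scenario × method: bias `δ = mean(x̂) − x`, empirical SE,
MSE, coverage of the 95% CI, and the rejection rate of the two-sided
test at α = 0.05 (Type I error when x = 0, power otherwise), each with
its Monte Carlo standard error. The full factorial design is 5 effects ×
3 grids × 6 sample sizes (100–1600) = 90 scenarios.

Common random numbers: the pre-shift latent draws are keyed only by
`(seed, n, rep)`, so every effect size and every grid reuses the exact
same base samples, and results are independent of execution order.

## Worked example

One simulation cell — 4-level grid, very large effect (x = 22), total
n = 400, 200 repetitions:

```python
import prosim as ps

spec = ps.ScenarioSpec(mu=50, sigma=22, effect_x=22.0, n=400,
                       grid=ps.grid_from_label("RE4"), nsim=200, seed=42,
                       scenario_id="x22_RE4_n400")
estimates, perf = ps.run_scenario(spec)
print(perf[["method", "mean_estimate", "bias", "emp_se", "mse",
            "coverage", "rejection_rate", "n_missing"]]
      .round(3).to_string(index=False))
```

```
method  mean_estimate   bias  emp_se     mse  coverage  rejection_rate  n_missing
   mlr         21.156 -0.844   2.230   5.661     0.945           1.000          0
 tobit         26.096  4.096   2.894  25.105     0.725           1.000          0
median         13.573 -8.427  15.931 323.537     0.055           0.435          0
```

Reading this: MLR slightly underestimates the latent effect of 22
(discretisation + ceiling attenuate the observed difference) but keeps
near-nominal coverage; Tobit *over*-corrects on a coarse 4-level scale
(mean estimate ≈ 26, coverage collapses); median regression is erratic
on so few distinct values — its estimates jump in multiples of the
33.3-point gap between adjacent scores, inflating the empirical SE and
MSE and destroying coverage.

## Running the full study

```
prosim run --out results/full              # all 90 scenarios, nsim=5000
prosim run --config study.yaml --nsim 500  # restricted/quicker designs
prosim summarise results/full              # wide mean-estimate table
prosim plot results/full --kind line --measure coverage
```

`run` writes tidy `estimates.csv` (one row per repetition × method),
`performance.csv` (one row per scenario × method), a `manifest.json`
with the config and package versions, and `run.log`. The full default
study takes a few hours on one CPU; any single scenario runs in
seconds-to-minutes.

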