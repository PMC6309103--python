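# Methods

## The measurement problem

A participant's interval-timing performance mixes at least three noise
sources: the internal clock, the memory representations the clock's output
is compared against, and motor execution. `clockvar` implements an
estimator of the clock component from a short task that involves no memory
updating and no feedback — 20 repeated productions of a 1-s interval — and
a validation protocol that checks whether the estimator predicts
prior-reliance in a separate multi-duration reproduction task.

## Production-task model and estimators

Analyzed productions are modeled per participant as

y_t = mu + b·t + e_t,   e_t ~ N(0, (nu·mu_t)^2),

where `mu` is the internal 1-s representation, `b` a slow linear drift per
trial, and `nu` the clock coefficient of variation (scalar property: noise
SD proportional to the timed duration). The first two trials of a session
are "start-up" trials — longer and more variable — and are removed before
any statistic is computed; the surviving trials are recoded 1..18.

Estimators (per participant, defaults):

* `sd` — sample SD, denominator n−1.
* `drift_slope`, `drift_intercept` — OLS of production on recoded index.
* `rmsr` — sqrt(RSS/n), the literal mean squared residual of that fit.
  The n denominator (not n−2) keeps the estimator the plain second moment
  of the detrended series; an `rmsr_denominator="n-2"` variant exists for
  degrees-of-freedom-matched comparisons. With these defaults
  `rmsr <= sd` holds for every dataset with n ≥ 3, since RSS ≤ centered SS
  and n > n−1.
* `scaled_rmsr` — rmsr / mean production; dimensionless, invariant under
  rescaling all productions, and the estimator of `nu`. Its square has
  expectation nu²·(n−2)/n under the model, so at n=18 the root-mean-square
  of scaled RMSR converges to nu·sqrt(16/18); a `df_corrected` flag
  removes that factor when an unbiased squared estimate is wanted.

Screening: a participant is excluded when at least 5 analyzed productions
exceed 3 s — repeated aberrant productions indicate non-compliance rather
than clock noise. The count and limit are configurable.

`implied_total_drift` converts a per-trial slope to a session-level drift
in ms by multiplying by the number of analyzed trials (18), the convention
used when reporting drift ranges for this design (even though trials 3→20
span 17 steps); it is a reporting convention, not an estimator.

## Reproduction task and the Bayesian observer

Presented durations are 1.17 / 1.4 / 1.68 s, 40 of each per 120-trial
block, two blocks. Responses faster than 0.5 s or slower than 2.5 s are
removed (strict inequalities; boundary responses kept), then presented and
reproduced durations are centered on 1.4 s and each participant's
central-tendency slope is the OLS coefficient of reproduced on presented
duration: 1 = veridical, 0 = the same response regardless of the stimulus.

The synthetic generator drives reproduction with a static-prior Bayesian
observer: percept x ~ N(d, (nu·d)²), estimate
e = λ(d)·x + (1−λ(d))·prior_mean with
λ(d) = prior_sd² / (prior_sd² + (nu·d)²), response ~ N(e, (motor_cv·e)²),
all draws truncated below at 0.05 s (a physically plausible minimum
keypress latency). The expected OLS slope has the closed form

slope = Σ (d−d̄)·m(d) / Σ (d−d̄)²,   m(d) = λ(d)·d + (1−λ(d))·prior_mean.

Note the prior-mean term contributes: λ varies across levels (longer
durations have wider likelihoods), so the constant-prior pull is stronger
on long durations. The naive form Σ(d−d̄)λ(d)d/Σ(d−d̄)², which drops that
term, disagrees with simulation by a factor of ~6 at typical parameters;
the full form matches the Monte-Carlo mean slope within sampling error and
is what `expected_central_slope` returns. It is 1 at nu=0, strictly
decreasing in nu (for the default prior centered on the design mean), and
tends to 0 as the likelihood becomes uninformative.

## Generator defaults (the simulated study conditions)

One cohort = 63 participants, order condition alternating by participant
parity. Population hyperparameters, chosen once to mirror the magnitudes
observed with this design:

| parameter | default | rationale |
|---|---|---|
| clock_cv | U(0.05, 0.25) | spans precise to noisy young-adult clocks |
| mu_one_second | U(0.7, 1.2) s | covers the observed order-condition means (~0.76–0.98 s) |
| drift_slope | N(−0.0055, 0.02), truncated to (−0.03, 0.05) s/trial | mean matches the observed mean slope; truncation keeps the 18-trial mean path positive |
| startup_mean_factor / cv_factor | 1.8 / 2.5 | start-up trials are much longer and more variable |
| motor_cv | 0.05 | small scalar execution noise |
| prior_mean | 1.4167 s (design mean) | static prior centered on the experienced durations |
| prior_sd | 0.2 s | comparable to the design's duration spread |

What the generator does **not** emulate: attention lapses and fast guesses
(so the 0.5–2.5 s outlier filter removes ~0% of synthetic trials, versus a
small percentage in real data), sequential trial-by-trial prior updating
(the prior is static within a session), non-linear or long-memory drift,
counting strategies, and any additive (non-scalar) noise floor. Passing
tests therefore validate the estimators and the inferential chain under
scalar-noise assumptions; they do not certify behavior under lapse
contamination or non-scalar noise.

## Default-prior Bayes factors

All inference uses default (objective) priors, computed in log space.

* **One-sample t-test** (`bf_one_sample`): Cauchy(0, r) prior on the
  standardized effect, r = √2/2 by default. The Cauchy is integrated as a
  normal mixture with InverseGamma(1/2, r²/2) on the relative prior
  variance g; the one-dimensional integral over log g is evaluated by
  adaptive quadrature after factoring out the integrand's maximum. The
  result depends on the data only through (t, n).
* **Correlation** (`bf_correlation`): stretched-beta prior on ρ with width
  κ (κ=1, i.e. uniform on (−1,1), by default). The marginal likelihood
  uses the exact sampling density of the sample correlation coefficient
  (hypergeometric form), so the Bayes factor depends only on (r, n).
  Posterior median, MAD and the 90% credible interval are read off a
  4001-point grid posterior. ρ and r are kept 1e−9 inside (−1, 1); sample
  correlations are clipped at |r| = 1−1e−8, so exactly collinear input
  yields a finite, astronomically large BF rather than an overflow.
* **Nested mixed models** (`bf_model_comparison`): y = centered reproduced
  duration; candidate fixed effects are centered presented duration, task
  order (sum-coded), a per-participant clock measure, and the
  measure × duration interaction (the term that carries "noisier clock ⇒
  flatter slope"); all fixed covariates are z-scored and share one g with
  an InverseGamma(1/2, r_f²/2) prior, r_f = 0.5. The participant random
  intercept has its own g (r = 1). The grand mean and σ² carry flat and
  Jeffreys priors and are integrated analytically (Woodbury identities on
  the p+J dimensional capacity matrix). The random-intercept g is
  integrated by a Laplace approximation on the log scale — with hundreds
  of trials per participant that integrand is extremely peaked, and the
  approximation error largely cancels between models; the fixed-effect g
  is integrated by adaptive quadrature around a coarse-grid mode. Pairwise
  BFs are ratios of marginal likelihoods, so transitivity holds to
  floating-point precision. A `bic` backend (BF ≈ exp(−ΔBIC/2) from a
  profile-likelihood ML fit of the same random-intercept model) provides a
  fast directional cross-check.

Numerical choices: quadrature relative tolerances 1e−10 (1-d tests) and
1e−7 (model marginals), reported per result as `numerical_error`; BFs
whose log exceeds 700 are reported as `inf` with label "extreme" rather
than overflowing. Evidence labels follow the Jeffreys bands (anecdotal /
moderate / strong / very strong / extreme), inverting BFs below 1 first.

Exact agreement with any particular off-the-shelf Bayes-factor package is
not claimed: random-effect integration schemes differ (Laplace +
quadrature here versus Monte Carlo sampling elsewhere), and the model
comparison is validated directionally on simulated ground truth plus
internally against brute-force grid-quadrature oracles.

## Pipeline, sizes, and determinism

`run_pipeline` executes simulate (or load CSVs) → start-up removal →
screening → variability measures → outlier filter → centering → slope
fits → drift t-test, measure-vs-slope correlation, and the model ladder
(intercept-only ⊂ +duration ⊂ +order ⊂ +measure ⊂ full). All randomness
derives from one master seed via spawned generator streams; identical
configs produce byte-identical report bodies (no timestamps in reports).

Validation problem sizes (the package's own choices, stated for
reproducibility): estimator-ordering checks use 2,000 simulated
participants; parameter recovery 5,000; the observer-model grid 800
sessions per (clock_cv, prior_sd) cell; the headline replication 200
cohorts for the correlation sign and 100 cohorts for the model-comparison
preference, each cohort at the full 63 × (20 + 240)-trial design.

## Known limitations

* The observer's prior is static; real reproduction data show sequential
  effects the generator does not produce.
* The Laplace step assumes a unimodal random-intercept integrand; for
  designs with very few trials per participant the quadrature backend's
  random-effect integration would need revisiting.
* Degenerate cohorts (participants left with <3 usable trials or one
  presented level) are dropped with logged warnings, not modeled.
* The RMSR denominators create a known ~6% mean offset between SD and RMSR
  even without drift (degrees of freedom, not bias in the squared scale);
  comparisons between the two use the df-matched variant where that
  matters.
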