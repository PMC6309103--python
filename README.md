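# clockvar

Estimating the noisiness of the internal clock from a handful of trials is
a recurring need in developmental and clinical timing research, where long
psychophysical sessions are impractical. `clockvar` implements and
validates a fast clock-variability measure: participants produce a
well-engrained 1-s interval 20 times, and the trial-to-trial variability of
those productions — after removing start-up trials and a slow linear drift
— indexes the noise of the internal clock.

## The measures and the validation logic

For each participant's analyzed productions $y_1,\dots,y_n$ (trial index
$t = 1..n$ after dropping the first two start-up trials):

* **SD** — sample standard deviation, $\sqrt{\sum_t (y_t-\bar y)^2/(n-1)}$;
  overestimates clock noise when the internal 1-s representation drifts.
* **RMSR** — root mean squared residual around the participant's OLS drift
  line $y_t \approx a + b\,t$: $\sqrt{\tfrac1n\sum_t \hat\varepsilon_t^2}$.
* **scaled RMSR** — RMSR divided by the mean production. Timing noise grows
  proportionally with the timed duration (the scalar property), so the
  dimensionless ratio is the clock's coefficient of variation.

Validity is assessed against the central-tendency (Vierordt) effect in a
multi-duration reproduction task (1.17 / 1.4 / 1.68 s, two blocks of 120
trials): reproductions regress toward the mean of the experienced
durations, and under Bayesian-observer accounts the strength of that
regression is governed by clock noise. With a Gaussian prior
$\mathcal N(\mu_p, \sigma_p^2)$ and a scalar likelihood of width
$\nu d$ around the presented duration $d$, the observer reports the
posterior mean

$$e(d) = \lambda(d)\,x + (1-\lambda(d))\,\mu_p,\qquad
\lambda(d) = \frac{\sigma_p^2}{\sigma_p^2 + (\nu d)^2},$$

so the per-participant regression slope of reproduced on presented duration
falls from 1 (noise-free clock) toward 0 as $\nu$ grows. A valid clock
measure must therefore correlate negatively with that slope, and a mixed
model carrying the measure must out-predict one without it.

The package ships:

* a **synthetic cohort generator** implementing exactly this observer model
  (scalar clock noise, linear drift, inflated start-up trials, scalar motor
  noise), with the closed-form expected slope as an analytic oracle;
* the **production / reproduction processing** stages (start-up removal,
  aberrant-producer screening, response-time outlier filter, centering,
  per-participant OLS fits);
* **default-prior Bayes factors** computed from first principles in log
  space: a JZS one-sample t-test, a uniform-prior correlation test with
  grid posterior summaries, and nested linear mixed-model comparison under
  mixture-of-g priors with a participant random intercept.

## Worked example

```python
from clockvar import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
print(report.to_text())
```

prints (abridged):

```
clockvar analysis report
  config hash: 9c0f1df03248ed56  seed: 1
  participants: 63 in, 63 kept, 0 excluded
  reproduction outliers removed: 0 of 15120 (0.00%)
  mean scaled RMSR: 0.1502
  drift (one-sample test on |slope|): BF10 = 5.163e+12 [extreme]
  mean central-tendency slope: 0.4720
  scaled RMSR vs slope: r_median = -0.851, MAD = 0.024, 90% CI (-0.900, -0.782), BF10 = 3.137e+16 [extreme]
Model comparison (quadrature backend)
  intercept_only                   logML=6513.196  log BF vs intercept_only: +0.000  [inconclusive]
  duration                         logML=10322.637  log BF vs intercept_only: +3809.441  [extreme]
  duration_order                   logML=10319.115  log BF vs intercept_only: +3805.919  [extreme]
  duration_measure                 logML=10839.975  log BF vs intercept_only: +4326.779  [extreme]
  full                             logML=10836.809  log BF vs intercept_only: +4323.613  [extreme]
```

Reading this: 63 simulated participants all pass screening; their drift
slopes are reliably non-zero (so detrending matters); the mean
central-tendency slope is 0.47 (well below the veridical 1); the scaled
RMSR correlates strongly negatively with the slope (noisier clocks, flatter
slopes); and the mixed model including the clock measure beats the
duration-only model by hundreds of log units, while adding task order is
(correctly) penalized — order never enters the generative model.

The same analysis is available from the shell:

```sh
clockvar run-all --seed 1 --out out/ --no-figures
clockvar simulate --seed 2 --out data/ --n-participants 63
clockvar measure-production --production-csv data/production_trials.csv --out out/
```

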