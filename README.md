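# frfit

Functional-response estimation for prey-depletion feeding trials.

## The problem

A consumer's *functional response* (FR) — how its per-capita feeding rate
changes with prey density — is a standard currency for comparing the
ecological impact of predators, for example hatchery-stocked sterile
triploid trout against diploid conspecifics. The canonical experiment
offers single predators a range of prey densities in closed arenas for a
fixed time and counts the prey eaten. Because eaten prey are not
replaced, prey density falls during the trial, and naive disc-equation
fits are biased. Rogers' **random predator equation** corrects for
depletion:

    N_e = N_0 * (1 - exp(a * (N_e * h - T)))

where `N_e` is the number of prey eaten, `N_0` the initial prey density,
`a` the attack rate, `h` the handling time, and `T` the trial duration.
The equation is implicit in `N_e`; on the principal branch of the
**Lambert W** function it has the closed form

    N_e = N_0 - W0(a * h * N_0 * exp(-a * (T - h * N_0))) / (a * h)

The package implements, for one predator group at a time and for whole
multi-group experiments:

- **type classification** — binomial logistic regression of the
  proportion of prey consumed on prey density; a significantly negative
  first-order term labels the response hyperbolic (Type II), a
  significantly positive first-order term followed by a significantly
  negative second-order term labels it sigmoidal (Type III);
- **maximum-likelihood fitting** of `(a, h)` under the depletion-corrected
  binomial likelihood, with the derived maximum feeding rate `1/h`
  (prey per trial period);
- **nonparametric bootstrap** (row resampling, default n = 2000) for 95%
  confidence intervals on the parameters and per-density confidence
  clouds around the fitted curves;
- **simulation** of complete feeding experiments, including predator-free
  control arenas, for power analysis and estimator validation.

Time is trial-normalised: one 4-h trial = 1.0 time unit, so `h` is in
trials per prey item and `1/h` is "prey per 4 h".

## Worked example

```python
import frfit

trials = frfit.simulate_trials(frfit.trout_design(seed=42))
report = frfit.run_pipeline(trials, frfit.PipelineConfig(seed=1, n_boot=500))
print(report.controls.message)
cols = ["fish_type", "novelty", "fr_type", "first_order_term",
        "attack_rate", "handling_time", "max_feeding_rate"]
print(report.to_frame()[cols].to_string(index=False))
```

prints

```
prey survival in predator-free controls was 100%; experimental deaths attributed to predation

      fish_type   novelty fr_type  first_order_term  attack_rate  handling_time  max_feeding_rate
  brown_diploid not_novel type_II         -0.093369     4.471249       0.037380         26.752176
  brown_diploid     novel type_II         -0.095817     4.586796       0.071306         14.023999
 brown_triploid not_novel type_II         -0.140217  2980.957987       0.099161         10.084648
 brown_triploid     novel type_II         -0.151023  2980.957987       0.088716         11.271929
rainbow_diploid not_novel type_II         -0.120514     6.715483       0.087338         11.449732
rainbow_diploid     novel type_II         -0.109127    12.434174       0.108992          9.174986
```

Every group is labelled Type II (negative first-order term), handling
times recover the generating magnitudes well, and `max_feeding_rate` is
exactly `1/handling_time`. The very large attack rates in the triploid
rows illustrate a real statistical feature of this design: when the true
attack rate is high, nearly all prey at low densities are eaten and the
likelihood becomes flat in `a`, so the point estimate is unstable while
`h` (set by the high-density plateau) stays well identified — which is
why the bootstrap intervals matter. `report.bands` holds the tidy
(group, density, lower, point, upper) table used to draw confidence
clouds around the fitted curves.

The `examples/` directory has one short narrative script per capability;
the same functionality is exposed as a thin CLI:

```
frfit simulate --preset-paper --seed 5 --out trials.csv
frfit analyze trials.csv --seed 11 --n-boot 2000 --out-prefix report
frfit report report.json --fmt tsv
```

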