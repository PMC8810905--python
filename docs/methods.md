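# Methods

## Model

The package models closed-arena feeding trials in which a single
predator depletes a fixed initial stock of prey over a trial of length
`T`. The expected consumption follows Rogers' random predator equation,
the depletion-corrected form of the Type II (Holling disc) response:

    N_e = N_0 * (1 - exp(a * (N_e * h - T)))

`a` (attack rate) scales the instantaneous encounter rate with remaining
prey density; `h` (handling time) is the time cost per captured prey,
during which no searching occurs; `1/h` bounds the feeding rate over the
trial. The equation assumes random search, no predator satiation within
a trial, constant `a` and `h` across the trial, and no prey replacement.

Time is trial-normalised: `T = 1` is one 4-h arena trial, `h` is in
trial-durations per prey item, and `1/h` is prey per trial period. This
is the only convention under which the published maximum-feeding-rate
cells equal the reciprocal of the published handling times (e.g.
`h = 0.100 -> 1/h = 10.000` prey per 4 h).

### Closed-form solution

The equation is implicit in `N_e`. On the principal branch of the
Lambert W function (`w * e^w = x`, `w >= -1`),

    N_e = N_0 - W0(a*h*N_0 * exp(-a*(T - h*N_0))) / (a*h)

Lambert W is evaluated in-package by Halley iteration from a series
guess near the branch point, a `log(x) - log(log(x))` guess for large
arguments and `log1p(x)` in between, to a relative identity tolerance
of 1e-12. The likelihood hot path uses a dedicated solver for
`W0(exp(lx))` (Newton on `w + log w = lx`), because the W argument
`a*h*N_0*exp(-a(T - h N_0))` overflows double precision for steep
responses; all arguments are therefore handled in log space. Arguments
below `e^-45` short-circuit to `W0(z) = z`, exact at double precision.
Degenerate parameters take analytic limits rather than the W form
(which divides by `a*h`): `a = 0` gives 0 and `h = 0` gives exponential
depletion `N_0(1 - exp(-aT))`. Floating-point undershoot of the branch
point `-1/e` is clamped.

## Type classification

Response shape is classified from a grouped-binomial logistic
regression of (eaten, surviving) on initial density. Grouped counts —
not pre-computed proportions — are used so density-1 trials contribute
exactly. The decision rule is sequential: the linear-only model is
fitted first; a significantly negative density coefficient labels the
group Type II. Only when the linear term is significantly *positive* is
the quadratic model fitted, and a significantly negative quadratic term
then labels the group Type III; any other pattern is inconclusive.
The sequential order is a documented design choice (a joint fit is the
main alternative); `alpha` defaults to the conventional 0.05 and is a
parameter everywhere. Fits are delegated to statsmodels GLM; complete
separation and non-finite coefficients are surfaced as errors rather
than returned.

## Maximum-likelihood fitting

Each trial's eaten count is treated as `Binomial(N_0, p)` with
`p = N_e(a, h, N_0, T) / N_0`. A grouped binomial likelihood was chosen
over least squares because counts at low densities are small integers
(0 or 1 at `N_0 = 1`). The negative log-likelihood is minimised over
`(log a, log h)` — enforcing positivity — with L-BFGS-B inside the box
`log a in [-12, 8]`, `log h in [-12, 5]`, from a fixed 3x3 grid of
heuristic starts (`h0` from the high-density consumption plateau
`T / mean eaten`, `a0` from the low-density depletion slope
`-log(1 - proportion eaten)/T`, each scaled by 1/4, 1, 4). Fixed starts
and no internal randomness make fits bit-reproducible; rows are sorted
canonically first so trial order cannot perturb floating-point sums.

Standard errors come from the inverse observed information (central
finite-difference Hessian of the NLL at the optimum, relative step
1e-4). Wald p-values are computed on the natural scale by the delta
method (`z = a / se(a)`), matching how starred attack-rate and
handling-time columns are conventionally reported; they are documented
as approximate — the sampling distribution of `a` in particular is
skewed at this sample size.

Identifiability guards: fewer than two distinct densities or all-zero
consumption raise typed errors (the likelihood is maximised on the
`a -> 0` boundary in the latter case); optimiser failure from every
start raises, carrying the best point found, rather than silently
returning a non-converged fit.

### Likelihood evaluation cost

Trials are collapsed to unique `(N_0, T)` cells (at most 6 in the
standard design): the binomial log-likelihood depends on the data only
through per-cell sums plus a parameter-free combinatorial constant, so
each objective call costs one Lambert evaluation per cell. This is what
makes the resampling experiments (tens of thousands of refits) cheap.

## Bootstrap

Uncertainty is nonparametric: trial rows are resampled with replacement
to the original sample size (18 rows per group in the standard design)
and refitted; 2000 replicates by default. Resampling is unstratified by
default, matching common practice when the published analysis does not
state stratification; a stratified-by-density option exists. Resamples
with fewer than two distinct densities or zero total consumption are
unidentifiable and are redrawn (counted and logged); replicates whose
refit fails are dropped, and more than 20% failures raises an
instability error. Intervals are 95% percentile by default, with a
bias-corrected-and-accelerated (BCa) option (jackknife acceleration
over rows). Curve bands are per-density 2.5%/97.5% quantiles of the
replicate predicted curves over a density grid — the documented choice
among cloud constructions, with the replicate draws exposed for any
alternative. Replicate refits warm-start at the point estimate and fall
back to the full multi-start grid on failure; on simulated data this
gives coverage identical to all-multi-start refits at roughly a ninth
of the cost.

Each pipeline group derives its bootstrap seed from the run seed and a
CRC of the group label, so results are deterministic and unaffected by
which other groups are present.

## Synthetic data

The simulator emulates the trout-fry/chironomid arena experiment: 3
fish types x 2 prey-novelty levels x 6 densities (1, 2, 4, 8, 16, 32)
x 3 replicates of 4-h trials, plus 3 predator-free control arenas per
density, with the published `(a, h)` point estimates per group as the
generating truth. Two mechanisms:

- `binomial` (default): eaten ~ `Binomial(N_0, N_e/N_0)` around the
  Rogers expectation. This matches the fitting likelihood, so parameter
  recovery isolates estimator behaviour from model misspecification.
- `event_driven`: a continuous-time search/handle renewal process
  (exponential encounter times at rate `a x` remaining prey, blocking
  handling intervals of length `h`, run to `T`). It shares the model's
  mean structure only asymptotically and is used for robustness checks;
  its captures can never exceed `min(N_0, ceil(T/h))`.

Controls draw from the background-mortality rate, 0 by default — the
experimental observation (100% control survival) — so control rows are
always zero-eaten unless a robustness run sets the rate positive.

What the simulator does *not* emulate: individual variation among
predators (each trial is independent; the real experiment may have
reused individuals across densities), within-trial satiation or
learning, arena edge effects, and overdispersion beyond binomial.
Passing recovery tests therefore demonstrate estimator correctness
under the model's own assumptions, not robustness to every feature of
live-animal data.

## Statistical behaviour at the experimental design, and limitations

Simulation at the published design shows a sharp asymmetry between the
two parameters:

- Handling time is well identified (median relative error ~7-11% across
  the published parameter rows): the high-density cells pin the plateau.
- The attack rate is well identified only when it is moderate
  (`a ~ 4-6`: median relative error ~20-23%). For the steep groups
  (`a ~ 14-41` with `h ~ 0.1`), virtually every prey at densities 1-4
  is eaten (`p > 0.999`) and the high-density cells are handling-limited,
  so the likelihood is flat in `a` above roughly 20 and the MLE can run
  away to the optimiser bound. This is an information limit of the
  design (18 trials, saturating low-density cells), not an optimiser
  artefact — the fitted point dominates a surrounding likelihood grid.
  Comparisons of steep attack rates at this design should rely on the
  bootstrap intervals, not point estimates.
- Percentile bootstrap intervals for `a` undercover somewhat at this
  sample size (~80% observed against 95% nominal in simulation),
  consistent with the skewed, weakly identified sampling distribution;
  BCa improves the endpoints but cannot manufacture information the
  design does not contain.

Problem sizes used in the validation experiments: 200 simulated
experiments per parameter row for recovery, 200 for classification,
100 experiments x 500 bootstrap replicates for coverage — sizes at
which the Monte Carlo error on the reported rates is a few percent.

## Numerical conventions

- Binomial success probabilities are clipped to `[1e-12, 1 - 1e-12]`
  inside the likelihood.
- Ties among multi-start optima resolve to the first (fixed) start
  order; equal-likelihood refits are therefore reproducible.
- Reported report values are rounded to 6 significant decimals when
  serialised; JSON reports are key-sorted so byte-identical output is a
  meaningful determinism check.
- `eaten > N_0`, negative counts and non-positive durations are rejected
  at read time with file line numbers.
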