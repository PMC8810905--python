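"""Maximum-likelihood fit of Rogers' random predator equation.

Simulates one group's feeding trials at the experimental design
(6 densities x 3 replicates, 4-h trials), fits attack rate and handling
time by maximum likelihood, and bootstraps 95% confidence intervals.
"""

import frfit
from frfit.simulate import SimDesign, TROUT_GROUP_PARAMS

key = ("brown_diploid", "novel")
truth = TROUT_GROUP_PARAMS[key]
trials = frfit.simulate_trials(SimDesign(seed=4, true_params={key: truth}))

fit = frfit.fit_rogers(trials, group=key)
boot = frfit.bootstrap_fr(trials, n_boot=2000, seed=5, fit=fit)

print(f"true parameters:     a = {truth.attack_rate}, h = {truth.handling_time}")
print(f"fitted attack rate:  a = {fit.params.attack_rate:.3f}  "
      f"(95% CI {boot.ci_a[0]:.3f} - {boot.ci_a[1]:.3f}, p = {fit.p_a:.2e})")
print(f"fitted handling:     h = {fit.params.handling_time:.4f}  "
      f"(95% CI {boot.ci_h[0]:.4f} - {boot.ci_h[1]:.4f}, p = {fit.p_h:.2e})")
print(f"max feeding rate:    1/h = {fit.max_feeding_rate:.2f} prey per 4-h trial")
print(f"log-likelihood:      {fit.loglik:.3f} over {fit.n_trials} trials")
print()
print("Handling time is tightly identified by the high-density plateau;")
print("the attack rate is wide because low-density trials saturate quickly.")
print("The band table (boot.band) holds per-density 2.5/97.5% prediction")
print("quantiles for plotting a confidence cloud around the fitted curve.")
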