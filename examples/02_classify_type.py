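"""Functional-response type classification.

Simulates depletion-driven feeding trials and classifies the response
shape from the binomial logistic regression of proportion consumed on
prey density: a significantly negative linear (first-order) term means
the proportion eaten falls with density — the Type II signature.
"""

import frfit
from frfit.simulate import SimDesign, TROUT_GROUP_PARAMS

key = ("brown_diploid", "novel")
design = SimDesign(seed=21, reps_per_density=20, control_reps=0,
                   true_params={key: TROUT_GROUP_PARAMS[key]})
trials = frfit.simulate_trials(design)

result = frfit.classify_fr_type(trials, alpha=0.05)
print(f"trials used:        {result.n_trials}")
print(f"first-order term:   {result.first_order:.4f}  (p = {result.p_first:.2e})")
print(f"classification:     {result.label}")
print()
print("A negative density coefficient on the logit of proportion eaten")
print("indicates a hyperbolic (Type II) functional response; a positive")
print("one followed by a negative quadratic term would indicate Type III.")
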