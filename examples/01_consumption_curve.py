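"""Expected consumption under prey depletion.

Evaluates the depletion-corrected Type II consumption curve (Rogers'
random predator equation, solved via the Lambert W function) for a
brown-trout-like predator, and shows the handling-time ceiling.
"""

import frfit

# published magnitudes for diploid brown trout fry on novel prey:
# attack rate 4.72 per trial, handling time 0.063 trials per prey
params = frfit.FRParams(attack_rate=4.72, handling_time=0.063)

print("prey offered -> expected prey eaten in one 4-h trial")
for n0 in (1, 2, 4, 8, 16, 32):
    ne = frfit.predict_consumed(params, frfit.TrialGeometry(n0, duration=1.0))
    print(f"  N0 = {n0:2d}   N_e = {ne:6.3f}")

print(f"\nmaximum feeding rate 1/h = {params.max_feeding_rate:.3f} prey per trial")
print("The curve decelerates towards the handling-limited ceiling T/h:")
print("doubling prey density less than doubles consumption (Type II shape).")
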