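"""Hidden-state versus observation-based probability learning.

Both learners count outcomes under a symmetric Dirichlet prior; they
differ at the resampling boundary, where the color->payoff legend changes
but the bin's composition does not. The hidden-state learner keeps its
counts; the observation learner starts over.
"""

import urnlearn as ul

hidden = ul.init_beliefs(2, variant="hidden_state")
observ = ul.init_beliefs(2, variant="observation")

# stage 1: ten one-sided draws of color 0
for state in [0] * 10:
    hidden = ul.observe(hidden, state)
    observ = ul.observe(observ, state)
print("end of sampling stage:")
print("  hidden-state estimates:", ul.point_estimates(hidden).round(3))
print("  observation estimates: ", ul.point_estimates(observ).round(3))

# resampling boundary: payoffs are re-assigned to colors
hidden = ul.stage_transition(hidden)
observ = ul.stage_transition(observ)
print("start of resampling stage:")
print("  hidden-state estimates:", ul.point_estimates(hidden).round(3),
      "(evidence kept)")
print("  observation estimates: ", ul.point_estimates(observ).round(3),
      "(back to the equiprobable prior)")

print("\nAfter ten one-sided draws the pre-update predictive probability "
      f"of the frequent color is {ul.predictive_probability(hidden, 0):.3f} "
      "= 11/12 and of the rare color "
      f"{ul.predictive_probability(hidden, 1):.3f} = 1/12.")
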