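"""Simulate one subject's session of the bin-sampling gamble task.

Nine bins (three each with 2, 5 and 10 colors), two sampling stages per
bin with 10-14 draws, then six priced buy/pass choices per stage.
"""

import numpy as np

import urnlearn as ul

rng = np.random.default_rng(1)
session = ul.simulate_session(ul.TaskDesign(), rng)

print(f"bins: {len(session.bins)}  draws: {len(session.draws)}  "
      f"choice trials: {len(session.trials)}")
bc = session.bins[0]
print(f"\nbin 0 has K={bc.K} colors with true probabilities {bc.theta}")
print(f"stage-1 color->payoff map: {bc.payoffs[0]}")
print(f"stage-2 color->payoff map: {bc.payoffs[1]} (re-randomized)")

# choices are generated separately, from any model in the family
session = ul.simulate_choices(
    session, "M4", ul.DEFAULT_GENERATING_PARAMS["M4"], rng
)
active = [t for t in session.trials if t.condition == "active"]
print(f"\nactive trials: {len(active)}, "
      f"buy rate {np.mean([t.decision for t in active]):.2f}")
print("The buy rate reflects loss-averse prospect-theory valuation of each "
      "gamble against its posted price.")
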