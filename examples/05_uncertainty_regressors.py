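"""Export the trial-wise uncertainty covariates as a BIDS-style event table.

Stimulus rows carry the pre-update probability of the observed payoff and
its prediction error; decision rows carry the gamble's expected value,
outcome entropy and choice entropy; feedback rows carry the net payoff.
"""

import numpy as np

import urnlearn as ul

rng = np.random.default_rng(3)
session = ul.simulate_session(ul.TaskDesign(), rng)
session = ul.simulate_choices(session, "M4",
                              ul.DEFAULT_GENERATING_PARAMS["M4"], rng)

events = ul.build_event_table(session, "M4",
                              ul.DEFAULT_GENERATING_PARAMS["M4"])
print(events.head(16).round(3).to_string(index=False))
print(f"\n{len(events)} events: "
      f"{(events.trial_type == 'stimulus').sum()} stimuli, "
      f"{(events.trial_type == 'decision').sum()} decisions, "
      f"{(events.trial_type == 'feedback').sum()} feedbacks.")
print("Modulators are mean-centered within subject; stimulus probability "
      "is computed before the belief update, so rare payoffs carry low "
      "values (surprise) and frequent ones high values.")
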