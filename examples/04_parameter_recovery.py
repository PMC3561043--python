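"""Parameter recovery: simulate from known values, refit, measure error.

A small replicate count keeps this example quick; the test suite runs the
full 50-replicate study.
"""

import urnlearn as ul

gen = ul.DEFAULT_GENERATING_PARAMS["M4"]
report = ul.parameter_recovery("M4", gen, n_subjects=23, replicates=5,
                               seed=7)

print("generating values:", gen)
print("median estimates: ",
      report.replicates[list(gen)].median().round(3).to_dict())
print("bias:", {k: round(v, 3) for k, v in report.bias.items()})
print("rmse:", {k: round(v, 3) for k, v in report.rmse.items()})
print("\nBias near zero and RMSE small relative to each value mean the "
      "study design identifies the model's parameters at this sample size.")
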