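# Methods

## Task model

A session consists of 9 bins; each bin holds balls of K ∈ {2, 5, 10}
colors with fixed but hidden probabilities θ. A bin is played in two
stages. In each stage, 10–14 balls are drawn with replacement and only the
payoff mapped to each ball's color is displayed; the color→payoff legend
(a bijection between states and K distinct integer payoffs) is visible
throughout, so the color can be inferred from the payoff by inverting the
legend. After the draws, six buy/pass choices are offered at prices drawn
continuous-uniform between the stage's minimum and maximum payoff; four
are *active* (outcome unknown when choosing) and two are *control*
(outcome known). Between stages the legend is re-randomized while θ is
unchanged.

Colors are assigned to probabilities at random when a bin is created
(implemented by permuting θ) and payoffs are assigned to colors at random
at each stage, which makes a state's probability orthogonal to its payoff
magnitude: across generated bins the mean correlation between θₖ and the
assigned payoff is zero (measured |mean r| < 0.01 over 2400 maps in the
acceptance run). Each choice trial's realized outcome is an independent
extra draw made at generation time, so active and control trials differ
only in whether the outcome is revealed before the decision.

### Generator defaults

* True probability vectors: K=2 → (0.7, 0.3); K=5 → (0.40, 0.25, 0.15,
  0.12, 0.08); K=10 → geometric decay with ratio 0.75, normalized. These
  are skewed distributions spanning low and high probabilities;
  configurable per bin.
* Payoff pool: distinct integers in [10, 99] (two-digit payoffs). An
  optional `payoff_pools` field cycles different pool widths across bins
  to manipulate payoff spread independently of state count.
* Prices continuous-uniform (not rounded to integers).
* One global seed; per-subject substreams are spawned deterministically
  from it (`numpy` SeedSequence), so cohorts are reproducible and
  subjects independent.
* 23 subjects × 9 bins × 2 stages × 4 active choices = 1656 active
  trials per cohort, the scale used for fitting and recovery studies.

### What the generator does and does not emulate

It reproduces the task's information structure (hidden states, legend
re-randomization, pricing) and generates choices from any model in the
family, so model comparison and recovery results measure identifiability
under the task design. It does not emulate human heterogeneity (one
parameter set per cohort), lapses or missed responses, reaction times,
session fatigue, or scanner timing. Passing recovery tests therefore show
the design identifies the models at this scale — not that real
participants behave like any of them.

## Learning rules

Count-based beliefs are held as integer tallies; point estimates
p̂ₖ = (nₖ + α₀)/(t + Kα₀) are computed on demand, so estimates are exact,
order-invariant, and free of incremental float drift. α₀ = 1 per state
(uniform Dirichlet): any symmetric α₀ yields the equiprobable prior mean,
and α₀ = 1 makes the extreme estimates after ten one-sided draws in a
two-color bin exactly 1/12 and 11/12. α₀ is exposed as a parameter.

The three count variants differ only at stage boundaries: hidden-state
counts persist across resampling, observation counts reset each stage
(within a stage payoffs and states are in bijection, so counting payoffs
is counting states), and the no-learning variant never updates. A new bin
always resets.

The delta-rule forecaster (M3) sets its forecast to the first payoff of a
stage and then moves it by η·(payoff − forecast) per draw. It is
re-initialized at both stage starts, because it forecasts payoffs and the
payoffs change at resampling. The end-of-stage forecast is evaluated in
closed form as a weighted sum of the stage's payoffs, which keeps the
likelihood cheap in η.

The *stimulus probability* regressor uses the estimate held **before**
incorporating the current draw. The pre-update convention makes the
extremes above (1/12, 11/12 ≈ 0.08, 0.92) attainable and matches the
"surprise" reading: a rare stimulus carries a low probability at the
moment it appears.

## Valuation and choice

Gambles are valued at the end of a stage's learning phase as
EV = Σₖ w(p̂ₖ)·v(xₖ − P) against a pass value of 0. The value function
uses one shared exponent α for gains and losses, matching the family's
parameter counts (M4 has exactly β₀, β₁, λ, α). The weighting function is
the one-parameter Tversky–Kahneman form with γ constrained to [0.3, 2] to
keep it monotone. Buy probabilities are clipped to [1e−9, 1−1e−9] before
logs. Control trials are generated but excluded from the likelihood: the
models describe valuation under outcome uncertainty, which the control
condition removes.

During sampling no price is posted, so prediction errors (the change in
EV from one draw) are computed price-free on subjective values of the raw
payoffs.

## Fitting

Nelder–Mead on the negative log-likelihood in an unconstrained space: log
transform for λ and α, scaled logit for γ ∈ [0.3, 2] and η ∈ [0, 1],
identity for β₀ and β₁. Five restarts with starting values drawn from
β₀ ~ N(0,1), β₁ ~ U(0.1,2), λ ~ U(0.5,3), α ~ U(0.3,1.2), γ ~ U(0.5,1.5),
η ~ U(0.1,0.9); the best restart is kept and the spread of restart optima
is reported (it is ≲1e−8 on well-sized data — the surface is smooth).
Simplex tolerances 1e−8 on parameters and function value, 5000 iterations
maximum. Fits are guarded against under-identification (≥ 10 active
choices per free parameter). Pooled fitting across subjects is the
default; per-subject fitting is available by passing single-session
datasets.

Model selection is strict minimum BIC with ties broken toward fewer
parameters. `compare_models` derives each model's restart stream from the
(seed, model tag) pair, so identical specs give identical rows and runs
are bit-reproducible.

Likelihood evaluation is vectorized: end-of-stage probability estimates
do not depend on fitted parameters, so they are precomputed once per
dataset and grouped by K; an evaluation is then a handful of array
operations, which keeps 50-replicate recovery studies inside minutes on
one CPU.

## Recovery studies

Parameter recovery simulates replicate cohorts from known values and
refits, reporting per-parameter bias and RMSE. Model recovery tabulates a
confusion matrix of BIC-selected versus generating model. The study
conditions are 23 subjects (1656 active choices) and 50 replicates in the
tests; the bundled examples use smaller counts for speed.

A known limitation, documented rather than patched: with M4-generated
data under the default skewed θ vectors, the no-learning model M4b is the
*worst*-fitting model, not the delta-rule model M3. The forecast absorbs
probability information implicitly through the payoff stream, while
uniform weights are badly wrong for skewed θ; which of the two trails
last is therefore a property of the (unobserved) true probability
vectors, and the package's defaults place M4b last by a wide BIC margin.
All other comparative facts — M4 selected over M4a/M4b/M3, the ordering
BIC(M4) < BIC(M4a) < BIC(M4b), and M5's weighting parameter penalized
when the generator weights linearly — hold in essentially every
replicate.

## Uncertainty regressors

Outcome entropy is Shannon entropy (−Σ p ln p, nats, 0·ln 0 = 0) of the
end-of-stage estimates; choice entropy is the binary entropy of the
model's buy probability. Natural logarithms throughout: base only rescales
a regressor, which is irrelevant after standardization. Event tables are
BIDS-style (onset, duration, trial_type, one column per modulator), one
row per draw/choice/stage-feedback, with synthetic onsets (1 s stimuli,
1 s gaps by default) and modulators mean-centered within subject. Entropy
uses the selected hidden-state learner's point estimates (not the
weighted probabilities of M5, whose fitted weighting is quasi-linear
anyway). No HRF convolution or GLM fitting is provided.

## Serialization

Sessions round-trip through three UTF-8 TSV tables: `draws.tsv`
(subject, bin, stage, t, state, payoff), `choices.tsv` (subject, bin,
stage, choice_idx, price, condition, decision, outcome), and `bins.tsv`
(true θ and both stages' payoff maps — needed because a never-drawn
state's payoff is not recoverable from the draw stream). Floats are
parsed with round-trip precision so write → read → write is
byte-identical. Study outputs embed the config hash (over the scientific
configuration, excluding output paths) and seed.
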