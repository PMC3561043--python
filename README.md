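# urnlearn

Hidden-state probability learning in a bin-sampling gamble task: task
simulation, a family of six choice models, maximum-likelihood fitting with
BIC comparison, and entropy-based uncertainty regressors.

## The problem

How do people learn the probabilities of uncertain outcomes from
experience, and do they track the *hidden causes* of what they see or just
the observations themselves? In the task this package models, balls are
drawn with replacement from a bin whose composition is hidden. Each ball's
color (a hidden state) maps to a displayed payoff via a legend shown to
the participant. After 10–14 draws the participant makes six priced
buy/pass decisions on a gamble (one more draw from the same bin); buying
yields the drawn payoff minus the price. The bin is then *resampled*: the
color→payoff legend is re-randomized while the color probabilities stay
fixed. A learner that tracks colors keeps its evidence across this
boundary; one that tracks payoffs must start over. Because payoffs are
assigned to colors at random, a state's probability is orthogonal to its
payoff magnitude by design — probability learning can be separated from
value.

The package is aimed at computational modelers of decision making: it
provides everything needed to simulate the task, generate choices from a
known model, fit competing models to choice data (simulated or supplied as
trial tables), and derive the trial-wise uncertainty covariates used in
model-based neuroimaging.

## Models

State probabilities are learned by counting under a symmetric
Dirichlet(α₀) prior; the posterior-mean estimate of state *k* after *t*
draws is

    p̂ₖ = (nₖ + α₀) / (t + K·α₀),   α₀ = 1 by default.

A gamble offered at price *P* over payoffs *x₁…x_K* is valued as

    EV = Σₖ w(p̂ₖ) · v(xₖ − P)

with the prospect-theory value function *v(x) = x^α* for gains and
*−λ(−x)^α* for losses (λ = loss aversion, α = diminishing sensitivity),
and the one-parameter Tversky–Kahneman weighting function
*w(p) = p^γ / (p^γ + (1−p)^γ)^{1/γ}*. The buy probability is the softmax
*q = logistic(β₀ + β₁·EV)*. Models are indexed by their number of free
parameters:

| tag | value | weighting | probability learning |
|-----|-------|-----------|----------------------|
| M2  | linear | identity | hidden states |
| M3  | linear | — | delta-rule payoff forecast (learning rate η) |
| M4  | prospect | identity | hidden states (counts persist at resampling) |
| M4a | prospect | identity | observations (counts reset each stage) |
| M4b | prospect | identity | none (equiprobable prior throughout) |
| M5  | prospect | curved (γ) | hidden states |

Fitting is pooled maximum likelihood over active choices via Nelder–Mead
with 5 random restarts; models are compared with
BIC = −2·MLL + k·ln(n), lower is better.

## Worked example

Simulate 23 subjects from M4 and let BIC re-select the generator
(`examples/03_fit_and_compare.py`):

```python
import urnlearn as ul

gen = ul.DEFAULT_GENERATING_PARAMS["M4"]   # β0=0.95 β1=0.54 λ=2.57 α=0.69
sessions = ul.simulate_cohort(ul.TaskDesign(), 23, "M4", gen, seed=42)
table = ul.compare_models(sessions, ["M2", "M3", "M4", "M4a", "M4b", "M5"],
                          seed=0)
```

```
model  n_params      mll      bic  beta0  beta1   lam  alpha  gamma  best
   M2         2 -459.437  933.699 -1.236  0.226   NaN    NaN    NaN False
   M3         3 -531.837 1085.910 -1.112  0.181   NaN    NaN    NaN False
   M4         4 -365.321  760.291  0.955  0.429 2.702  0.763    NaN  True
  M4a         4 -400.764  831.177  0.740  0.355 2.625  0.789    NaN False
  M4b         4 -525.953 1081.554  0.617  0.751 2.120  0.532    NaN False
   M5         5 -365.294  767.649  0.954  0.420 2.719  0.770  1.012 False
```

The generating model M4 wins on 1656 active choices and its parameters
come back near their generating values (λ ≈ 2.70 vs 2.57, α ≈ 0.76 vs
0.69). The observation learner M4a pays for restarting its counts at every
resampling boundary; the no-learning model M4b and the payoff-forecast
model M3 trail far behind; M5 matches M4's likelihood but its weighting
estimate is quasi-linear (γ ≈ 1.01), so the ln(n) penalty leaves it behind
M4 — learned probabilities are used nearly linearly.

The other examples cover task simulation, belief updating across the
resampling boundary, parameter recovery, and event-table export
(`examples/01_…` through `05_…`).

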