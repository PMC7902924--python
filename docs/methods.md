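# Methods

## The microworld

One participant plays 30 rounds.  At round `t` they hold a per-round income
(initially 292 EC), a property wealth (initially 20,000,000 EC), and invest a
fraction of the income in mitigation.  The landslide probability is the
convex blend `P(T) = We·P(I) + (1−We)·P(E)` with `We = 0.7`.  The
human-factor term is `P(I) = 1 − M · (cumulative investment / cumulative
budget)`, where the budget of a round is its (possibly damage-reduced)
income; full cumulative investment floors `P(I)` at `1 − M`.  The
environmental term `P(E)` stands in for rainfall and terrain susceptibility
jointly; no decomposition of it is modeled, and it is a configured scalar
(default 0.3) or per-round series.  `M` is a free parameter of the
environment (default 0.9).  Both defaults are package choices: the blend and
the floor are structural, but no published values exist for `M` or `P(E)`.

A landslide occurs when one uniform draw falls below `P(T)`.  If it occurs,
three independent Bernoulli draws decide property damage, injury and
fatality; a landslide with none of the three is benign.  Property damage
halves property wealth; injury multiplies income by 0.90; fatality by 0.80;
simultaneous injury and fatality compose multiplicatively (order irrelevant).
There is no recovery mechanism, so income is non-increasing over a
trajectory.  Damage probabilities per condition: low (0.03, 0.10, 0.01),
high (0.30, 0.90, 0.09), medium (0.165, 0.50, 0.05), for (property, injury,
fatality).

Round order is: observe income → invest → update probabilities → sample
landslide → apply damages → emit feedback.  The feedback of round `t` is the
win `W(t) = income_t − invest_t` and the non-negative loss magnitude
`L(t) = PD_t + income_drop_t`, where the income drop is the reduction caused
by damages sampled this round (it takes monetary effect from round `t+1`).
Total wealth is accumulated un-invested income plus property wealth, with no
interest or decay.  Currency values are kept as unrounded floats.

## Decision models

All models choose among ten half-open investment-ratio bins
`[(k−1)/10, k/10)` and then draw the ratio uniformly within the bin, so the
continuous decision variable inherits the bin distribution.  Expectancies
start at 50 units per bin; with all expectancies equal, the first choice is
uniform.  Feedback enters utility space after division by the initial income
(292), so a zero-investment, zero-damage round has scaled win exactly 1.
Without this scaling, property-damage losses (~10^7 EC) saturate the softmax
for any sensitivity, collapsing every model to determinism; the divisor is a
config argument of the agent step.

Two sign/initialization readings deserve note.  The linear EV valence is
implemented as `(1−w)·W − w·L`: `L` is a positive loss magnitude and `w` is a
loss-aversion weight, so losses must enter negatively for larger `w` to mean
"losses punish harder".  And the initial expectancy is 50 (the value under
which the calibration procedure is defined), not 0.

The EV family (EV, EV-PU) updates only the expectancy of the bin whose
feedback just arrived (the bin chosen in the previous round), by the delta
rule `EV_k ← (1−a)·EV_k + a·V`; sensitivity is `θ(t) = (t/10)^c` with the
round index of the decision being made.  The decay family (PVL, PVL-2)
decays all expectancies by `A` and adds the utility to the chosen bin;
sensitivity is `3^c − 1`.  The random model draws ten iid uniforms and takes
the argmax (ties, a measure-zero event, break to the lowest index).

Per-participant draw order is documented and fixed — choice draw(s), bin
draw, landslide draw, then damage draws (three when the landslide occurred) —
making every trajectory bit-reproducible from (model, parameters, condition,
seed).

## Synthetic cohorts

Human trajectory data for this task is not publicly deposited, so the
package generates cohorts in two modes.  *Model ground truth* runs agents
through the microworld (scalar reference path, one spawned RNG stream per
participant).  *Stylized human* adds independent Gaussian noise
(sd 0.15, clipped to [0,1]) around target mean curves chosen to match the
only published summaries: a flat 0.38 curve for the low condition, a
logistic rise from 0.3 toward 0.85 whose overall mean is solved to exactly
0.67 for the high condition, and a flat 0.52 midpoint curve for the medium
condition.  Default cohort sizes are 20 (low), 23 (high) and 30 (medium).
These cohorts reproduce the qualitative contrast (high above low, rising
vs. flat) but none of the round-to-round structure, autocorrelation or
individual differences of real participants — so passing end-to-end tests
demonstrates that the machinery works, not that any model fits humans.

A vectorized batch simulator evaluates a whole cohort with numpy array
operations and a single shared generator (fixed per-round draw blocks, with
damage draws always consumed so the count is round-invariant).  It is
mathematically the same process as the scalar path — cross-checked
statistically in the tests — and backs the calibration objective, where it
is ~100x faster.

## Calibration

The objective for a candidate parameter vector is `SSD1 + (1 − R²)` between
the simulated cohort's mean investment-ratio curve and the target mean
curve, where `SSD1` is the mean squared per-round deviation and `R²` the
squared Pearson correlation of the two curves.  Because the model curve is
stochastic, the objective uses common random numbers: a fixed set of
replicate seeds (default 5 replicates of as many simulated participants as
the target cohort), with the statistic computed per replicate and averaged.
This makes the objective deterministic in the parameters, so the search is
well-posed; the replicate count is exposed in `GAConfig`.

The optimizer is a real-coded genetic algorithm with the published run
settings (population 20, crossover rate 0.80, mutation rate 0.01, stall
limit 50 generations at relative tolerance 1e-8) and standard operator
choices where none are published: tournament selection of size 2, uniform
arithmetic crossover, Gaussian mutation with sd 10% of each parameter's
range and reflection at the bounds, and one-elite preservation (making the
best-so-far objective non-increasing).  A generation cap bounds runtime:
500 in the `full` profile, 30 in the `smoke` profile used by the test suite
and CLI default.  Parameter bounds: EV `a,w ∈ [0,1]`, `c ∈ [−5,5]`;
PVL/PVL-2 `α ∈ [0,1]`, `λ ∈ [0,5]`, `A ∈ [0,1]`, `c ∈ [0,5]`; EV-PU as PVL
but `c ∈ [−5,5]`.  The random model is a zero-dimensional search: its
objective is evaluated directly and its parameter count is 0.

Degenerate cases: when either curve is exactly constant the Pearson
correlation is undefined, and `R²` is defined as 1 if `SSD1 < 1e-12` and 0
otherwise, keeping the objective continuous.  `AIC1 = T·ln(SSD1) + 2p`
generalizes the 30-round constant to the curve length `T`; a zero `SSD1`
yields a `−inf` sentinel with a warning.  `R²` is squared correlation by
construction and therefore rewards anti-trending curves as much as trending
ones; this literal behavior is kept deliberately.

## Evaluation and workflow

The calibration experiment fits all five models separately to the low and
high cohorts and writes AIC1-sorted comparison tables plus block-mean curves
(six blocks of five rounds).  Generalization freezes the calibrated
parameters from each calibration condition and simulates the models in the
medium condition, producing a table with two parameter provenances per
model.  A run manifest (seeds, conditions, profile, paths) fully determines
every numeric output; rerunning a manifest reproduces the tables byte for
byte.

## Problem sizes

Default analysis sizes are those of the study conditions: 30 rounds, cohort
sizes 20/23/30, GA population 20.  The test suite and the acceptance script
use the `smoke` GA profile (generation cap 30; 5 objective replicates, 10
for recovery runs) and 10,000-round sampling checks; these sizes were chosen
as desk-scale defaults and are stated here so results can be rescaled.

## Known limitations

* **Loss-aversion identifiability.** In the high condition, scaled
  property-damage losses are ~3.4e4 before the power transform, so the
  utility of a damaged round is enormously negative for any `λ ≥ ~1`; the
  chosen bin is subsequently avoided regardless of `λ`, which therefore
  acts mainly through the rarer small (income-drop-only) losses.  Recovered
  `λ` values are correspondingly noisy, and the recovered ordering between
  a high-`λ` and a low-`λ` ground truth can flip at some seeds.
* The stylized noise model is independent across rounds; real participants
  autocorrelate.
* No per-individual fitting, no hierarchical estimation, no alternative
  information criteria — the analysis operates on cohort mean curves only.
* Clipping stylized trajectories to [0,1] biases the cohort mean slightly
  toward 0.5 when the target curve approaches the boundaries (about −0.01
  at a target of 0.85 with sd 0.15).
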