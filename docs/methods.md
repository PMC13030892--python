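# Methods

## The observer

Beliefs are conjugate Beta–Bernoulli: a flat Beta(1,1) prior per deck,
updated to Beta(1+c, 1+t−c) after observing c orange cards in t draws on that
deck.  Beliefs carry only the sufficient counts; the raw card sequences live
in the trial records.  The posterior over the table-level quantity
θ = sgn(π₁−π₂) is

P(θ=1|x) = ∫₀¹ f_{π₁}(z) F_{π₂}(z) dz,   P(θ=−1|x) = 1 − P(θ=1|x),

with f and F the Beta density and CDF.  Two evaluation paths: an exact finite
sum for integer pseudo-counts (the only case the simulation produces),

P(X>Y) = Σ_{i=0}^{a₁−1} B(a₂+i, b₁+b₂) / [(b₁+i) B(1+i, b₁) B(a₂, b₂)],

evaluated through log-beta functions and memoised; and adaptive
Gauss–Kronrod quadrature (absolute tolerance 1e−8) for general parameters.
The tests pin both paths against a 100,001-node trapezoidal oracle (≤1e−6
over every integer combination up to 25) and against 10⁶-draw Monte-Carlo
checks.

Uncertainty is the binary entropy H(θ|x) in nats, computed with the
0·ln 0 := 0 convention; a fresh table carries ln 2 ≈ 0.69 nats (1 bit).  EIG
of deck d is H(current) − [p·H(after orange) + (1−p)·H(after blue)] with
p the posterior-predictive orange probability; it is non-negative because
P(θ=1) is a martingale under the predictive and entropy is concave.  Table
EIG needs a convention for which deck the next card would come from; the
default (`max_over_decks`) takes the better deck, matching the normative
framing of learning as much as possible; `mean_over_decks` and
`least_sampled_deck` are provided.  Exposure is the table's total card count.

## Decision-variable orientation

Δ-EIG and Δ-uncertainty are right-minus-left.  The exposure *strategy's*
decision variable uses the least-exposure orientation (left-minus-right
counts), so that for every strategy a positive slope means
heuristic-consistent behaviour and the three fitted slopes are directly
comparable.  The generic `observer.delta_dv` helper remains literal
right-minus-left for all three quantities.  This orientation is what makes
the exposure epiphenomenon *negative*: uncertainty-driven agents revisit
hard-to-learn tables, i.e. choose the more-exposed option.

## The task generator

Defaults mirror the study conditions: 4 tables × 2 decks; four sessions of
1 practice + 3/5/5/5 experimental rounds (18 experimental rounds);
exploration lengths 10 + Geometric(1/44) on {1,2,…} (minimum 11, mean 54,
constant hazard after trial 10); practice rounds 12–19 trials, flagged and
excluded from every analysis; pair presentation uniform over the six
unordered table pairs with uniform side assignment; $0.25 per correct test
choice recorded in the config.  True proportions are drawn per deck from
{0.1, …, 0.9} (tenths, matching the ten-card reveal at test), resampled on
within-table ties so θ is always defined; the exact scheme behind the
original proportion lists is not published, so the grid is configurable.
Round lengths are drawn i.i.d. per participant rather than as a shuffled
shared list — the marginal distribution is identical and nothing downstream
conditions on the shared-list structure.

## Agents

The generative choice rule mirrors the fitted model exactly:

logit P(right) = β_side + β_rep·r + s(U)·z(ΔDV),
s(U) = β_dv + β_int·max(0, U − τ)  (hinge; a step variant ships behind
`threshold_form="step"`),
P = (1−lapse)·logistic(·) + lapse/2,

with r ∈ {+1, −1, 0} the repeat-option side (the offered table chosen more
recently this round; 0 before either has been chosen) and U the summed
entropy of the two offered tables in nats.  The hinge is the default because
a slope *change per nat* is the only reading under which an interaction
coefficient of order 10¹–10² is dimensionally sensible against a moderator
that spans at most 2 ln 2 ≈ 1.39 nats.

z-scoring constants are a generator property, not a dataset afterthought:
the raw ΔDVs are divided by calibration constants (standard deviations
measured once from a 60-participant random-exploration run at the default
task configuration: 0.0149 nats for ΔEIG, 0.2918 nats for Δ-uncertainty,
4.778 cards for Δ-exposure; means are 0 by symmetry).  The constants are
stored in each dataset's metadata and reused by `prepare_predictors`, so
generation and fitting share one scale and slope recovery is exact up to
sampling noise.  Empirical z-scoring is available for data without metadata.

Deck choice within the chosen table follows the agent's `deck_policy`
(default: the deck with higher EIG, ties split at random); how humans picked
decks was never analysed, so this is a free simulation choice.  The test
phase has no published generative model; the simulator answers with the MAP
value of θ with probability equal to the posterior maximum (probability
matching), which yields chance accuracy at the entropy ceiling and
near-perfect accuracy at zero entropy without extra parameters.  Confidence
is an equal-width bin of the posterior maximum on [0.5, 1] into 1–5.
A question is "unsolvable" when a deck was never sampled; fully fresh tables
always land in the lowest confidence bin.

## Inference

The multilevel Bayesian machinery of the original analysis (HMC, ~10³
posterior draws per model) is replaced by a deterministic two-stage scheme:
ridge-penalized maximum likelihood per participant (Newton iterations with
step-halving; λ = 1 on the standardized scale, playing the role of a
standard-normal prior and guaranteeing finite estimates under separation;
SEs from the inverse penalized Hessian) and an inverse-variance-weighted
population summary.  Model comparison replaces PSIS-LOO with exact
participant-stratified k-fold cross-validation (default k = 10); the score
is summed held-out log predictive density, with pairwise SEs over fold-level
differences, and folds whose held-out responses are single-class are merged
into a neighbour.  Ranking ties (within machine precision) break toward the
simpler strategy (exposure < uncertainty < EIG).  Model recovery simulates
replicate cohorts per generating strategy and counts winners.

## Threshold model

For each τ on a grid (0.30 to 2 ln 2 nats, step 0.005 by default) the
piecewise model is refit with the hinge regressor max(0, U−τ)·z(Δu); τ̂ is
the grid argmax of the penalized profile likelihood (the likelihood is
non-smooth in τ, so a grid keeps the optimum exactly reproducible;
neighbouring grid points warm-start each other).  Slope SEs are conditional
on τ̂.  When no trials lie above τ̂ the interaction is unidentifiable and is
fixed at 0 with a flag.  The avoidance score integrates the shortfall of
s(U) below β_low from τ̂ to 2 ln 2: ½·|β_int|·(2 ln 2 − τ̂)² for the hinge
(a rectangle for the step variant), 0 when β_int ≥ 0.  Individual fits share
the group grid and add the pooled profile, scaled by 1/n_participants, as a
log-prior — one average participant's worth of pooled evidence, which
stabilizes τ for individuals with few high-uncertainty trials.  The
approach/avoid association is the Pearson correlation between individual
β_low and avoidance scores, with a two-sided permutation p-value.

## Problem sizes

The recovery studies run at two scales chosen once: strategy recovery at
30 participants × 6 rounds × 20 replicates per generator (the scale at which
the three correlated decision variables are still reliably separable), and
threshold recovery at 194 participants × 18 rounds × 20 replicates with the
0.005-nat grid.  The analysis drivers use 30 × 6 cohorts for strategy
inference and a 100 × 18 cohort for the threshold and test-phase analyses.

## What the generator does and does not emulate

Passing recovery on these synthetic cohorts shows that the estimation
pipeline is consistent for data produced by its own generative family under
the study's structural conditions (schedule, round lengths, pair
presentation, Bernoulli outcomes).  It does not establish anything about
phenomena the generator omits: reaction times and their sequential-sampling
structure, memory decay or forgetting, within-round colour semantics,
participant attrition, or any systematic deviation of human choice from the
logistic family.  Real-data coefficient values are therefore out of scope
here; the synthetic studies mirror the qualitative and recovery claims only.

## Known limitations

- The population summary is two-stage, not jointly hierarchical; with very
  few trials per participant the inverse-variance weights understate
  between-participant variance.
- Ridge shrinkage biases per-participant slopes toward 0 by roughly
  λ/(λ + Fisher information); at the default scales this is ≤ 2% and well
  inside the recovery tolerances, but it is visible if λ is raised.
- τ̂ inherits the grid resolution; SEs for τ are not reported (profile
  curvature at a grid argmax is not a reliable variance estimate).
- The avoidance score extrapolates the fitted hinge to the U = 2 ln 2
  ceiling even when few trials lie near it.
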