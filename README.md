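# cardexplore

Simulation and analysis of **uncertainty-guided exploration** in an
incremental-learning card task, built for computational-cognition researchers
who want to test *how* people decide what to learn about next when no reward
is at stake.

## The task and the model

An agent explores a room of four tables, each holding two decks of cards.
Each card is one of two colours; deck *i* contains an unknown proportion
π<sub>i</sub> of "orange" cards, and the thing to learn on each table is
θ = sgn(π₁ − π₂) — which deck is richer in orange.  On every exploration
trial two random tables are offered; the agent picks one, flips one card from
one of its decks, and updates its beliefs.  After a shifted-geometric number
of trials (minimum 11, mean 54) the round ends with a test: pick the richer
deck on every table, rate your confidence.

A conjugate **Bayesian observer** tracks each deck with a Beta posterior
(flat Beta(1,1) prior; after *c* orange cards in *t* draws, Beta(1+c, 1+t−c))
and derives, per table:

- **P(θ = 1 | x) = ∫₀¹ f<sub>π₁</sub>(z) F<sub>π₂</sub>(z) dz** — the posterior
  that deck 1 is richer;
- **uncertainty H(θ|x) = −Σ P log P** in nats (0.69 nats = 1 bit for a fresh
  table);
- **expected information gain (EIG)** — the expected drop in H from the next
  card, under the posterior predictive;
- **exposure n<sub>x</sub>** — cards seen on the table so far.

Three candidate exploration strategies order the two offered tables by the
right-minus-left difference in one of these quantities (for exposure, the
*least-sampled* orientation): choose by ΔEIG (normative), by Δ-uncertainty
(simpler), or by Δ-exposure (simplest).  Agents choose through a logistic
rule with a side intercept, a repeat-option bias, a lapse mixture and —
optionally — an **overall-uncertainty threshold** τ: above τ (the sum of the
two tables' entropies), the Δ-uncertainty slope changes by β<sub>int</sub>
per nat, turning approach into avoidance.  The package fits all of this back
from simulated choices: ridge-penalized logistic models per strategy,
exact k-fold cross-validated model comparison, a profile-likelihood fit of τ,
and the **avoidance score** ½·|β<sub>int</sub>|·(2ln2 − τ)² (the triangular
area above the declining segment of the piecewise effect curve).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts, writing tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py     # simulate the four cohorts
python analysis/02_strategy_inference.py   # which DV explains choice?
python analysis/03_model_recovery.py       # confusion matrix of strategies
python analysis/04_threshold_model.py      # piecewise threshold model
python analysis/05_testphase_validation.py # accuracy vs end-of-round entropy
```

Step 02 prints, for the uncertainty-driven cohort (planted slope 1.0):

```
eig          dv slope +0.479 (SE 0.026)
uncertainty  dv slope +0.918 (SE 0.030)
exposure     dv slope -0.179 (SE 0.017)
ranking: uncertainty > eig > exposure
exposure epiphenomenon: slope -0.179 (SE 0.017) -> negative, as predicted
```

The fitted Δ-uncertainty slope recovers the planted value; the negative
exposure slope is the epiphenomenon the simulation demonstrates: agents that
approach uncertainty keep returning to harder-to-learn tables, so their
choices anti-correlate with the least-exposure heuristic.  Step 04 prints

```
tau_hat = 0.990 nats (planted population mean 1.0); 42.2% of trials above
beta_low = +0.931 (SE 0.009); beta_int = -15.65/nat (SE 0.18); avoidance area = 1.229
approach-avoid correlation across 100 participants: r = 0.434 (permutation p = 0.0005; planted rho = 0.5)
```

— the profiled threshold lands on the planted 1.0 nats, the above-threshold
reversal is recovered in sign and order of magnitude, and the planted
coupling between approaching and avoiding uncertainty survives individual-
level estimation.  Step 05 shows binned test accuracy falling from 0.99 in
the lowest-entropy bin to 0.49 at the entropy ceiling (chance), with a
logistic slope of −5.4 (SE 0.2) of accuracy on entropy.

A config-driven end-to-end run (simulate → fit → compare → threshold →
validate, with a JSON report) is available as a CLI:

```bash
cardexplore demo --out demo_run           # ~5 s, recovers the planted strategy
cardexplore run-all --config my.yaml --seed 7 --out my_run
```

## Layout

- `src/cardexplore/` — the library: `task`, `observer`, `agents`,
  `inference`, `threshold`, `testphase`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers (see above).
- `tests/` — pytest suite, including property-based tests (hypothesis) and
  the end-to-end recovery studies in `tests/test_acceptance.py`.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details and known limitations.
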