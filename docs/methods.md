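# Methods

## Problem and model

`wormqsar` builds binary QSAR classifiers for chronic reproductive toxicity
of pesticides to earthworms. The endpoint is the reproductive NOEC
(no-observed-effect concentration, mg of compound per kg of soil); compounds
with NOEC below 100 mg/kg — the UN boundary for the least-harmful category —
are *toxic*, the rest *nontoxic*. Inputs are precomputed numeric molecular
descriptors (any descriptor table in CSV form); the package does not compute
descriptors itself.

The classification problem is doubly awkward: classes are imbalanced
(roughly 79:21 toxic:nontoxic), and endpoints arrive partly as interval
records. The pipeline addresses these with explicit curation rules, random
under-sampling of the majority class before every fit, metrics robust to
imbalance (Balanced Accuracy, MCC, Brier score), and an abstaining ensemble
that defines an applicability domain.

## Endpoint curation

NOEC records are either real values or intervals in a small text grammar
(`50`, `>100`, `<100`, `>0-10`, `>10-100`, `<100-inf`; explicit bound
structs are also accepted). Classification at breakpoint `bp = 100` follows
one containment rule: an interval entirely below `bp` is toxic, entirely
at/above `bp` is nontoxic, and an interval that straddles `bp` is discarded
(it cannot be assigned a class). Real values map by `v < bp` / `v >= bp`.
This generalizes the full seven-rule conversion table, including the
discard of `>10-100` records (the closed upper bound sits exactly on the
breakpoint) and of unbounded-above records whose lower end lies below 100.
Unknown interval dialects fail loudly at parse time rather than being
guessed.

Identity curation is supported by two primitives: the Jaccard index between
binary circular fingerprints (any radius-6 Morgan-type fingerprint works;
fingerprint generation itself is delegated) and a predicate requiring more
than two per-identifier fingerprints to coincide exactly.

## Classifier

The base learner is a stochastic gradient-boosted tree ensemble for binary
outcomes: each weak, depth-limited tree is fit to the gradients (residuals)
of the running prediction on a per-tree random row subsample, only a random
fraction of descriptors is considered at each split, and the running
prediction moves by `shrinkage` times the tree output. Boosting stops when
the training loss has not improved by 1e-5 for 25 consecutive rounds, and
the ensemble is truncated at the best round. LightGBM supplies the boosting
loop (single-threaded, deterministic mode, seeded); the wrapper embeds the
training descriptor schema so prediction inputs are validated by name, and
persists models as a JSON envelope containing the model text plus schema.

Tunable hyperparameters, with defaults of the search space:

| parameter          | meaning                                   | range, scale        |
|--------------------|-------------------------------------------|---------------------|
| `shrinkage`        | learning rate per boosting step           | [0.01, 0.3], log    |
| `n_trees`          | maximum boosting rounds                   | [50, 500], integer  |
| `feature_fraction` | descriptors considered per split          | [0.1, 1.0]          |
| `row_fraction`     | compounds bagged per tree                 | [0.5, 1.0]          |
| `max_depth`        | weak-learner depth                        | [1, 5], integer     |

Shallow trees and row/feature subsampling are deliberate: the learners are
kept weak so the ensemble, not any single tree, carries the fit.

Hyperparameters are tuned by a budgeted sequential search (default 32
evaluations, 8 in the nested GA benchmark): a seeded random initial design
of half the budget (at most 8 points), then a Gaussian-process surrogate
(Matérn 5/2 + white noise on the unit cube, objective values standardized)
proposing the expected-improvement maximizer over 256 seeded candidates. If
the surrogate fit fails the iteration degrades to a random draw, preserving
the exact evaluation budget. The objective is the mean out-of-fold Brier
score of 5-fold cross-validation in which each fold's training part is
under-sampled before fitting — the Brier score is used because the pipeline
optimizes for calibrated probabilities, which the stacked ensemble then
consumes. Folds are stratified when the fold count does not exceed the
minority-class count, plain otherwise (so leave-one-out on tiny balanced
sets still runs).

## Descriptor selection

Feature selection is a wrapper GA over binary masks. Defaults: population
50, 20 generations (10 in the scaled benchmark), initial masks with an
expected 10 set bits. Per generation, a seeded partition sends 50% of
individuals into uniform crossover (paired; each position swapped with
probability 0.5), 10% into per-bit mutation (flip probability 1/n), and
leaves 40% unchanged, mutually exclusively; an odd crossover count moves
one individual to the unchanged group, and masks emptied by an operator are
repaired with one random bit. The per-position swap and flip probabilities
are conventional uniform-crossover/1-per-genome choices and are exposed in
the config.

Every individual is scored on five objectives: MCC and Brier score on both
the training and validation parts of a fresh 80/20 resample of the modeling
pool (the split is shared by all individuals of a generation and redrawn
every generation, so selection cannot overfit one split), plus the
parsimony reward `P(d) = 1/(1+d)` on the mask size. The training part is
under-sampled to class balance before fitting; metrics are computed on the
full imbalanced parts. Hyperparameters are re-tuned only for masks an
operator actually changed — an unchanged descriptor set keeps its tuned
values — and all individuals are re-scored on each generation's resample.

Survivors are selected by NSGA-II (fast non-dominated sorting, crowding
distance on the split front, boundary points at infinite distance, ties
broken by input position) from the parents+offspring pool back to the
population size. The canonical minimization vector is
`(-MCC_train, -MCC_val, BS_train, BS_val, -P)`. Standard crowding distance
is retained despite its known degradation in many-objective settings; at
five objectives and these population sizes it behaves acceptably and is
cross-checked against a brute-force oracle in the tests.

A two-slot hall of fame tracks the best individual by validation
Specificity and by validation Sensitivity (MCC breaking ties): the
specificity-oriented model (Model A) suits workflows where clearing a
compound matters most, the sensitivity-oriented model (Model B) suits
conservative risk screening. There is no convergence criterion beyond the
fixed generation budget.

## SHAP interpretation

Explanations use the kernel formulation of Shapley values. For a model over
M descriptors, every non-trivial coalition (all 2^M when M <= 15, a
kernel-distributed sample otherwise) is mapped to descriptor space by
keeping the explained compound's values where the coalition has 1s and
imputing 0 positions from a seeded random background row (full-row draws,
16 replicates by default, averaged). Coalitions are weighted by the Shapley
kernel `(M-1) / (C(M,s) * s * (M-s))`; the empty and full coalitions enter
as equality constraints (`g(empty) = mean background prediction`,
`g(full) = f(x)`), so the efficiency identity `beta0 + sum(beta) = f(x)` is
exact by construction. The weighted least-squares problem is solved by
eliminating the last coefficient against the constraint. With a single
background row the imputation is deterministic and the solution provably
equals exhaustive-enumeration Shapley values; the test suite verifies this
elementwise to 1e-6 for M up to 8. Descriptor importance is the mean |SHAP|
across explained compounds, ties broken alphabetically.

## Ensemble applicability domain

The stacked score is `(p_A - 0.5) + (p_B - 0.5)`, i.e., the sum of the two
models' probabilities normalized to zero at their individual 0.5 decision
thresholds. Verdicts use two thresholds `t_non <= 0 <= t_tox`: toxic when
`score > t_tox`, nontoxic when `score < t_non`, otherwise *outside the
applicability domain*. Inequalities are strict, so at thresholds (0, 0) an
exact tie abstains — this keeps the abstention region closed and decisions
reproducible. Coverage is the fraction of compounds receiving a verdict and
is non-increasing as either threshold widens.

The threshold surface is scanned on a default grid of 0.02 steps over
`t_tox in [0, 1]` and `t_non in [-1, 0]`, recording coverage and the
metrics of the covered compounds (missing where a class vanishes inside the
domain). The operating point maximizes balanced accuracy subject to a
coverage floor (default 0.70), preferring larger coverage and then narrower
thresholds on ties. If no grid cell reaches the floor, the pipeline falls
back to (0, 0) with a warning rather than aborting.

Note the equivalence used throughout: because SHAP values satisfy
efficiency, the sum of a model's SHAP values equals its prediction minus
the baseline, so thresholding the summed probabilities and thresholding
summed SHAP values coincide up to the baseline constant. The probability
formulation is primary in this package.

## Y-scrambling

Chance correlation is assessed by refitting the full training procedure on
label-permuted copies of the modeling pool (default 100 repeats, label
marginals preserved, fresh 80/20 resample per repeat) and recording
validation metrics. A genuine model's validation MCC should exceed the 95th
percentile of the scrambled distribution, whose mean should be statistically
indistinguishable from zero.

## Synthetic benchmark

The generator emulates the structure of a curated pesticide endpoint table
at desk scale. Defaults (fixed once, used by all seeded benchmarks): 449
compounds, 300 descriptors, toxic fraction 355/449, 8 informative
descriptors of which 2 are nonlinear, a 5-column correlated block, 5
constant columns, unit noise, effect size 1.0 sd, 15% of NOEC records
emitted as intervals and 2% in breakpoint-straddling (discard) dialects.
Informative linear descriptors get a class-conditional Gaussian mean shift
(univariate AUC ≈ 0.76 at the default effect size); the nonlinear pair is
XOR-shaped — each margin is uninformative (AUC ≈ 0.5) but their sign
product tracks the class — so additive/linear baselines fail on them by
construction while depth-≥2 trees succeed; further nonlinear slots get
threshold effects. NOEC values are class-conditional lognormal (toxic
median 10, nontoxic median 1000 mg/kg, σ_log10 = 0.5), rejection-sampled
onto the correct side of 100 mg/kg so curation recovers the generating
label for every non-discarded record.

What the generator does *not* emulate: real descriptor marginals
(computed 2D descriptors are heavy-tailed, discrete, block-structured far
beyond one correlated factor), structure-driven label noise, activity cliffs, or
chemically meaningful descriptor names. A pipeline that passes the
synthetic benchmark is shown to *recover planted signal under imbalance and
redundancy*, not to reproduce real-data accuracy.

Benchmark problem sizes used by the tests and the acceptance script: a
449×300 data set split 302/147, GA with 50 individuals × 10 generations and
an 8-iteration Bayesian budget per re-tuned mask, 100 Y-scrambling repeats
at a reduced model size (100 trees, depth 3), and full-grid threshold scans.
On this benchmark the GA's hall-of-fame masks enrich planted descriptors
several-fold over their 8/300 base rate, and the abstaining ensemble's
balanced accuracy at ≥70% coverage is at least the full-coverage value.

## Numerical conventions and edge cases

- Sens/Spec are reported missing when their class is absent; Balanced
  Accuracy averages the defined components; MCC is 0 whenever a
  confusion-matrix marginal is zero. This keeps scrambled and
  tightly-thresholded evaluations stable.
- Published worked-example comparisons round to 2 decimals. One published
  ensemble metric column (MCC) does not recompute from its own printed
  confusion counts (0.70/0.26/0.50 from the counts vs 0.69/0.30/0.52 as
  printed); the internally consistent cells are used as oracles and the
  inconsistent column is excluded.
- All randomness flows from one global seed through stable SHA-256 stage
  hashes (31-bit), so adding a stage does not shift the randomness of
  existing stages and identical configs reproduce byte-identical reports.
- Degenerate GA resamples (a validation part missing a class) are redrawn
  with incremented seeds, at most 10 times.
- Empty descriptor masks are forbidden everywhere; operators repair them by
  setting one random bit.

## Known limitations

- The GA's five-objective crowding distance is a diversity heuristic, not a
  many-objective method; very large populations would warrant reference-
  point selection.
- Kernel SHAP with sampled coalitions (M > 15) is approximate; tree-exact
  SHAP is not implemented.
- The applicability domain is purely score-based; it does not model
  descriptor-space distance, so a compound far outside the training
  distribution can still receive a confident verdict.
- Under-sampling discards majority-class information; no reweighting or
  oversampling alternatives are provided (they performed worse in the
  motivating study).
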