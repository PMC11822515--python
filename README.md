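# wormqsar

Imbalanced-data QSAR classification of pesticide reproductive toxicity in
earthworms.

Earthworms are key indicator organisms for soil health, and chronic
reproductive toxicity — the reproductive NOEC (no-observed-effect
concentration, mg of compound per kg of soil) — is the preferred endpoint
for assessing pesticide risk to them. Measured NOECs are scarce, often
reported as intervals, and heavily imbalanced toward toxic compounds
(roughly 79:21 at the 100 mg/kg breakpoint that separates the least-harmful
category). `wormqsar` is a pipeline for building, validating, and
interpreting binary toxic/nontoxic classifiers from precomputed molecular
descriptor tables under exactly these conditions. It is aimed at
computational toxicologists and cheminformaticians who need a screening
model with an explicit applicability domain rather than a single opaque
classifier.

## What the pipeline does

1. **Curation** — NOEC endpoints (reals and interval dialects such as
   `>10-100` or `<100`) are converted to binary classes at breakpoint
   100 mg/kg: an interval entirely below the breakpoint is toxic, entirely
   at/above it nontoxic, and one that straddles it is discarded. Jaccard
   fingerprint comparison supports structure-identity checks.
2. **Classifier** — stochastic gradient-boosted trees (shrinkage η,
   per-tree row bagging, per-split feature subsampling, depth-limited weak
   learners, training-loss plateau stop), always fit on a randomly
   **under-sampled** (class-balanced) training set. Hyperparameters are
   tuned by a budgeted Gaussian-process Bayesian search over 5-fold CV,
   minimizing the out-of-fold Brier score
   `BS = (1/|C|) Σ_c (Pr(ŷ_c) − y_c)²`.
3. **Descriptor selection** — a genetic algorithm over binary descriptor
   masks: per generation 50% of individuals cross over, 10% mutate, 40%
   pass unchanged; the modeling pool is resampled 80/20 each generation;
   each mask is scored on five objectives (MCC_train, MCC_val, BS_train,
   BS_val, and the parsimony reward `P(d) = 1/(1+d)`) and survivors are
   chosen by NSGA-II. A hall of fame keeps the best mask by validation
   specificity (Model A) and by validation sensitivity (Model B).
4. **Interpretation** — kernel SHAP: for each compound the prediction is
   decomposed as `f(x) = β₀ + Σ_i β_i` by solving the Shapley-kernel
   weighted least-squares problem over coalitions
   (`π(z′) = (M−1)/(C(M,|z′|)·|z′|·(M−|z′|))`), with stochastic
   background-row imputation for missing coalition members. With full
   enumeration this equals exact Shapley values.
5. **Validation** — Y-scrambling: the whole training procedure is refit on
   label-permuted data (default 100×) to establish the chance-performance
   null that a genuine model must beat.
6. **Applicability domain** — Models A and B are stacked additively,
   `score = (p_A − 0.5) + (p_B − 0.5) ∈ [−1, 1]`; a compound is toxic if
   `score > t_tox`, nontoxic if `score < t_non`, and otherwise *outside the
   applicability domain* (no verdict). A grid scan over `(t_tox, t_non)`
   maps the coverage/performance trade-off and picks an operating point
   maximizing balanced accuracy at a coverage floor.

Because no public descriptor table ships with the package, a first-class
synthetic generator (`wormqsar.synthetic`) produces descriptor matrices
with the same statistical stressors — 79:21 imbalance, a few informative
descriptors (some XOR/threshold-shaped so linear models fail), correlated
and constant columns, interval-valued NOECs — so the entire pipeline is
testable end to end.

## Worked example

The metric layer reproduces published-style confusion arithmetic. For a
test-set confusion matrix TP=64, TN=27, FP=7, FN=49:

```python
from wormqsar import ConfusionCounts, compute_metrics, coverage, classify_with_ad

rep = compute_metrics(ConfusionCounts(tp=64, tn=27, fp=7, fn=49))
print(f"Sens={rep.sens:.2f} Spec={rep.spec:.2f} Acc={rep.acc:.2f} "
      f"BalAcc={rep.balacc:.2f} MCC={rep.mcc:.2f}")
print(f"coverage = {coverage(107, 147):.3f}")
for s in (0.71, -0.16, -0.30):
    print(s, classify_with_ad(s, t_tox=0.14, t_non=-0.23).verdict.value)
```

prints

```
Sens=0.57 Spec=0.79 Acc=0.62 BalAcc=0.68 MCC=0.30
coverage = 0.728
0.71 toxic
-0.16 outside_AD
-0.3 nontoxic
```

Read: the classifier finds 57% of toxic compounds (sensitivity) and 79% of
nontoxic ones (specificity); balanced accuracy 0.68 averages the two, and
MCC 0.30 summarizes the whole matrix under imbalance. With dual thresholds
(0.14, −0.23), 107 of 147 test compounds (72.8%) fall inside the
applicability domain; an ensemble score of 0.71 is a confident toxic call,
while −0.16 lands between the thresholds and gets no verdict.

End-to-end on synthetic data, from the shell:

```bash
wormqsar simulate --seed 1 --outdir data/        # 449 x 300 benchmark table
wormqsar curate --noec data/noec.csv --out data/labels.csv
wormqsar run-all --seed 1 --outdir run/          # GA -> models A/B -> SHAP -> AD
wormqsar predict --bundle run/ --compounds new_compounds.csv --out decisions.csv
```

`run-all` writes `metrics_table.csv` (model × train/val/test rows with
Sens, Spec, Acc, BalAcc, MCC and confusion counts), `shap_importance.csv`,
`threshold_surface.csv`, `yscrambling.csv`, the persisted models, and
`summary.json`. The same workflow is available as a library via
`wormqsar.pipeline.run_pipeline(PipelineConfig(...))`.

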