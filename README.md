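# qgexar

**Q**ualitative **G**ene **ex**pression **A**ctivity **R**elationship
modeling: predicting whether a chemical disrupts endocrine signaling —
estrogen receptor (ER) binding, androgen receptor (AR) binding, thyroid
hormone receptor (TR) antagonism — from the differential gene-expression
signature it induces in human cell lines, instead of from its chemical
structure as a classical QSAR would.

The package is aimed at computational toxicologists working with
L1000-style signatures: chemical-by-gene z-score matrices measured in
two cell lines (an MCF7-like and an A549-like line), where each profile
covers 978 directly measured *landmark* transcripts plus statistically
inferred tiers (*best inferred*, recall > 0.95, and lower-confidence
*inferred* genes). Because the public activity and signature databases
involved cannot be redistributed, the package ships a seeded synthetic
generator that emulates their statistical structure (z-score features,
cell-line offsets, class imbalance, duplicate profiles and conflicting
activity records) with a known ground truth, so the entire protocol is
testable end to end.

## The protocol

For each endpoint and cell line, with activity label y ∈ {active, inactive}:

1. **Assembly.** Duplicate activity records for a chemical resolve to
   *active* on any contradiction; duplicate expression profiles resolve
   to the one with the highest transcriptional activity score (TAS).
   A shared validation set is sampled from the chemicals present in both
   cell lines; the rest of each cell line is its training set.
2. **Feature selection — MultiSURF.** A relief-family weight per gene:
   for each target instance *i*, near neighbors are those closer than
   T_i − D_i, where T_i is the mean distance from *i* to all others and
   the dead band D_i is half the standard deviation of those distances.
   Near *hits* (same class) decrease a feature's weight by the
   range-normalized value difference, near *misses* increase it
   (prior-weighted); genes with weight > 0 are retained.
3. **Nested cross-validation.** Inner 5-fold grid search and an outer
   repeated 10×5-fold CV, both scored by balanced accuracy
   BA = (SE + SP)/2, over a class-weighted model zoo (gradient boosting,
   random forest, SGD-SVM, elastic-net logistic regression, dense ReLU
   networks of depth 1–4). Selection and tuning see only each outer
   fold's training part.
4. **Consensus.** The final per-cell-line models predict the shared
   validation chemicals; the consensus probability is the mean of the
   two cell-line probabilities, called active when ≥ 0.5. Reported
   metrics: SE, SP, BA, MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
   and ROC AUC.
5. **Applicability domain.** A query is in-domain when its mean cosine
   similarity to the 3 nearest training signatures reaches
   Dc = ⟨y⟩ − Zσ (Z = 0.5 by default), where ⟨y⟩ and σ summarize the
   training chemicals' own leave-self-out top-3 similarities. Coverage/BA
   curves trace the reliability–coverage trade-off.
6. **Feature importance.** Per-gene Kruskal–Wallis tests between active
   and inactive chemicals; raw p < 0.05 genes are counted (no
   multiple-testing correction — descriptive by design) and the top-10
   lowest-p genes reported with the direction of the median shift.

## Worked example

```yaml
# run.yaml
endpoint: ER
synthetic:
  n_chemicals: 300
  n_landmark: 100
  n_best_inferred: 30
  n_inferred: 20
  n_informative: 10
  effect_shift: 2.0
tiers: [landmark]
models:
  - {algorithm: random_forest, grid: {n_estimators: [200]}}
  - {algorithm: logistic_elasticnet, grid: {C: [1.0], l1_ratio: [0.5]}}
repeats: 2
folds: 5
inner_folds: 3
n_validation: 60
seed: 42
out_dir: example_run
```

```bash
qgexar run-all --config run.yaml
```

This generates a 300-chemical two-cell-line cohort with 10 informative
genes shifted by 2 z-score units in actives, and runs the full protocol
(~8 s). Key artifacts it wrote:

`MCF7_cv_summary.tsv` — outer-CV model selection on the MCF7-like line:

```
algorithm            ba_mean  ba_sd
random_forest        0.908    0.040
logistic_elasticnet  0.870    0.061
```

Random forest wins on mean cross-validated BA in both cell lines (see
`manifest.json`, which also records the config hash and every derived
stage seed). MultiSURF retained 22 of 100 landmark genes on MCF7 and 27
on A549 — the planted 10 rank on top of both weight lists
(`*_feature_weights.tsv`).

`consensus_metrics.tsv` — the mean-probability consensus on the 60
held-out validation chemicals:

```
se     sp   ba     mcc    auc
0.917  1.0  0.958  0.932  0.959
```

i.e. the consensus recovers 91.7% of the active chemicals with no false
positives, balanced accuracy 0.958.

`MCF7_ad.tsv` — applicability domain per validation chemical, e.g.

```
chemical_id  mean_top3_cosine  Dc     in_domain
CHEM00002    0.514             0.389  True
```

and `MCF7_ad_curve.tsv` traces BA and coverage as the cosine cutoff
rises from 0 to 1.

The same stages are available individually (`qgexar simulate`,
`assemble`, `select-features`, `train`, `evaluate`, `consensus`, `ad`,
`importance`) and as library calls — see `qgexar.EndpointClassifier`,
`qgexar.MultiSURF` (a scikit-learn selector) and
`qgexar.CosineKNNApplicabilityDomain`, which compose with sklearn
pipelines and model selection.

## Methods

See `docs/methods.md` for the statistical model behind the generator,
the numerical conventions (tie-breaks, thresholds, degenerate inputs)
and known limitations.
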