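# Methods

This note records the statistical model, the numerical conventions and
the design choices behind `qgexar`, in the order the pipeline runs.

## Synthetic cohort generator

The generator emulates the statistical structure of L1000-style
differential-expression data for two cell lines with planted ground
truth. Its model:

* **Background.** z-scores are standard normal, independent per
  (chemical, gene, cell line). Real signatures are z-scores relative to
  plate controls, so N(0, 1) is the natural inactive background.
* **Signal.** A `prevalence` fraction of chemicals is active (default
  484/1552 ≈ 0.312, the ER prevalence in the MCF7-like dataset the
  generator mimics). Actives have `n_informative` genes (default 10)
  shifted by `effect_shift` z-units (default 2.0). Informative genes are
  drawn from the landmark tier first, overflowing into best-inferred
  only if requested, so landmark-restricted models see the full signal.
* **Cell-line divergence.** An additive offset per (gene, cell line),
  drawn N(0, `cell_line_offset_sd`) with default SD 0.5, applied to all
  profiles of that line. This separates the two cell lines in expression
  space without modeling any biology; 0.5 was chosen once as a visible
  but not dominant divergence (half the background SD).
* **Tier noise.** Genes in the low-confidence inferred tier have their
  noise SD doubled (`inferred_noise_factor = 2.0`), so models trained on
  all genes underperform landmark-only models — the qualitative behavior
  this package's tier-filtering stage exists to exploit.
* **TAS.** The transcriptional activity score is Uniform(0, 1) and
  independent of the label; it is only ever a deduplication key.
* **Duplicates and conflicts.** `inject_duplicates` gives a
  `duplicate_profile_rate` fraction of chemicals (default 5%) a second,
  noise-perturbed profile with a distinct TAS, and a
  `conflict_label_rate` fraction (default 5%) a second activity record
  with the opposite label. These defaults create enough collisions to
  exercise the cleaning rules without distorting the cohort.

What the generator does **not** emulate: gene–gene correlation,
pathway structure, dose–response or time dependence, heavy-tailed
z-score distributions, batch effects, or any relationship between TAS
and activity. Tests passing on synthetic cohorts therefore demonstrate
that the pipeline's machinery is correct and calibrated — not that the
reported real-data performance would be reproduced on LINCS-scale
inputs. Effect size and noise defaults are stated choices, not values
calibrated to real signatures.

## Assembly rules

* Conflicting activity records resolve to *active* (one positive report
  outweighs negatives); `n_sources` counts the raw records behind each
  resolved one and `had_conflict` marks contradictions. Resolution is
  idempotent.
* Duplicate profiles resolve to the highest TAS; exact ties keep the
  first profile in input order — an arbitrary but deterministic rule.
* The validation set is a *simple* random sample of the chemicals
  present in both cell lines (not stratified by label: the per-set
  active fractions in the data this mirrors differ between training and
  validation, which a stratified draw would not produce). Chemicals
  lacking a signature in one cell line simply do not enter that cell
  line's dataset.

## MultiSURF

Authored from scratch; the test suite checks it against an exhaustive
double-loop reference to 1e-10.

* **Distance.** Manhattan over features divided by their observed range
  (constant features contribute zero everywhere). The relief literature
  uses this normalized diff for continuous features; the choice is an
  assumption, stated here because the protocol description this package
  follows does not fix the metric.
* **Neighborhood.** Per target *i*: threshold T_i = mean distance to all
  others, dead band D_i = half the population SD of those distances,
  near(i) = {j : d_ij < T_i − D_i}. No far-neighbor term (plain
  MultiSURF, not MultiSURF*).
* **Update.** Per target, hit contributions are averaged over the near
  hits and subtracted; miss contributions are averaged per opposing
  class, weighted by P(class)/(1 − P(target class)) — a no-op for binary
  labels — and added. The total is divided by the number of instances,
  which makes weights independent of instance order.
* **Selection.** Strictly positive weights, sorted descending (stable
  for ties). An empty selection is possible on null data; the
  `MultiSURF` sklearn selector then degrades to the identity mask so a
  downstream model still has inputs, and the functional API returns the
  empty list for the caller to handle.

## Nested cross-validation and the model zoo

* Inner grid search: stratified k-fold (default 5) per grid point,
  scored by balanced accuracy; ties keep the first point in grid
  declaration order. A single-point grid short-circuits the search.
* Outer protocol: repeated stratified k-fold (10×5 at full scale).
  MultiSURF and the grid search are refit inside every outer fold on
  that fold's training part only. Folds are stratified (the protocol
  source is silent; stratification prevents empty-class folds under
  imbalance), and a minority class smaller than k raises rather than
  silently degrading.
* Class weighting: balanced sample weights (inverse class frequency on
  the fit partition) for gradient boosting, random forest, SGD-SVM and
  logistic regression. The dense networks are fit unweighted — they are
  not in the class-weighted family set, and `MLPClassifier` accepts no
  sample weights.
* The SVM family uses `SGDClassifier` with the modified-huber loss: a
  smoothed hinge that keeps the large-margin geometry while providing
  the predicted probabilities that consensus averaging and AUC require
  (plain hinge yields none).
* Gradient boosting is one family backed by xgboost; AutoML-style
  externals plug in through `register_external_model`, which accepts any
  sklearn-compatible classifier factory.
* Hyperparameter grids are package defaults, deliberately small; every
  grid is configurable per run.
* Features enter models as raw z-scores with no re-scaling (they are
  already standardized scores).

## Metrics

* Predictions threshold at 0.5 with "p ≥ 0.5 → active" (the tie goes to
  active, matching the conflict-resolution bias toward sensitivity).
* MCC uses the standard denominator (TP+FP)(TP+FN)(TN+FP)(TN+FN) and is
  0 by convention when any factor vanishes. SE or SP with an empty
  class is reported as NaN (undefined), never as 0 — a deliberate
  distinction between "no information" and "always wrong".
* BA = (SE+SP)/2 exactly; AUC is the trapezoidal ROC area (equivalently
  the Mann–Whitney U statistic over P·N, which the tests verify).
* CV aggregation: arithmetic mean and sample SD per metric; a single
  fold reports SD 0 by convention.

## Consensus

With exactly two models a majority vote is undefined on disagreement,
so the consensus is the arithmetic mean of the per-cell-line
probabilities, called active at ≥ 0.5. The mean is symmetric in cell
lines and bounded by the two inputs; the interface accepts any number
of models but the protocol (and tests) use two.

## Applicability domain

* ⟨y⟩ and σ are computed over the training chemicals' own mean top-3
  cosine similarities with **self excluded** — self-similarity is
  identically 1 and would bias ⟨y⟩ upward. σ is the population SD
  (ddof = 0); at these training sizes the ddof choice moves Dc by less
  than the seed-to-seed variation.
* Dc = ⟨y⟩ − Zσ with Z = 0.5 by default. A degenerate training set
  (σ = 0) warns and uses Dc = ⟨y⟩.
* Cosine similarity of signed z-score profiles can be negative; values
  are kept as-is rather than clamped, and coverage-curve thresholds in
  [0, 1] simply exclude them. (Descriptions of this score as "ranging
  from 0 to 1" hold only for non-negative data.)
* By default the AD operates on landmark + best-inferred features even
  when the classifier used selected landmarks only; this is
  configurable (`ad_tiers`).

## Feature importance

Two-group Kruskal–Wallis per gene (tie-corrected H, chi-square p with
1 df; identical values across both groups give H = 0, p = 1). **No
multiple-testing correction is applied** — the significant-gene count
at raw p < 0.05 is a descriptive protocol quantity, not an inferential
claim; treat it accordingly. Each record carries the direction of the
median shift in actives so over/under-expression statements are
reproducible. Top-k ranking breaks p-value ties by gene id.

## Orchestration and reproducibility

One global seed fans out to per-stage seeds by hashing stage labels
(SHA-256, reduced below 2^31), so any stage reruns identically in
isolation and rerunning a config reproduces byte-identical metric
tables. Every TSV artifact begins with a `# config_hash=` comment
naming the SHA-256 (truncated) of the canonicalized config; the
manifest records the config, the hash, all derived seeds, the package
version and per-stage summary counts.

## Test and acceptance problem sizes

The shipped tests and the acceptance script run the protocol at reduced
scale, chosen as the smallest sizes at which the checked statistical
properties are stable across seeds: parameter recovery uses 25
replicates of 300 chemicals × 150 genes (10 planted, shift 2.0); null
calibration uses 1000 genes for the significant-fraction check and a
160-chemical, 25-gene cohort with 5×5 outer CV for the chance-level
check across all eight model families; the end-to-end ceiling run uses
200 chemicals with shift 3.0 and conflict injection disabled, since
label corruption is an orthogonal stressor that would confound a pure
separability ceiling. Full-scale settings (10×5 outer CV, 978-gene
landmark tier, full grids) remain the library defaults.

## Known limitations

* The synthetic generator's independence assumptions make feature
  selection easier than on correlated real transcriptomes; selected-set
  sizes and capture rates on synthetic data are qualitative indicators
  only.
* Probabilities are not calibrated; the 0.5 threshold and the mean-
  probability consensus inherit whatever miscalibration the base
  learners have.
* The AD threshold assumes validation queries are exchangeable with
  training chemicals; distribution shift invalidates the coverage
  expectation long before it invalidates the similarity ranking.
* MultiSURF is O(n²p); at LINCS scale (thousands of profiles, ~10⁴
  genes) per-fold selection dominates runtime.
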