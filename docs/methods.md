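# Methods

This note records the models and procedures repelscreen implements, the
assumptions behind its synthetic-data generators, and the numerical and
design choices made where the problem left the design open.

## The screening model

The pipeline treats repellency prediction as a small-n QSAR problem: a
training table of a few hundred volatile chemicals, each described by
hundreds to thousands of numeric physicochemical descriptors, with a
continuous % repellency outcome (or a curated active/inactive label).
Two model generations are supported and are both expressible as
pipeline configs:

* **v1 — forward selection + SVM.** `sfs_select` greedily adds the
  descriptor that maximizes the *multiple correlation*: the Pearson
  correlation between the observed response and a least-squares fit on
  the candidate subset. "Maximize the correlation" is ambiguous for a
  subset; the joint-fit formulation handles redundancy and ties
  deterministically (ties break by feature name) and reduces to simple
  Pearson correlation for a single feature. A Spearman variant
  (identical search on rank-transformed data) is available by flag.
  The selected subset feeds an RBF-kernel SVM evaluated by repeated
  k-fold CV or repeated 80/20 splits with ROC analysis.

* **v2 — CV-RFE + model-averaged ensemble.** `cv_rfe` wraps recursive
  feature elimination in repeated k-fold CV. Per round (fold ×
  repeat): fit the learner on the training partition, compute
  importance, prune to each requested subset size in descending order
  (importance is *recomputed after every elimination step* — true
  RFE), and score each pruned model on the held-out partition (Pearson
  R for regression, AUC for classification). Averaging over rounds
  gives `performance_by_n`; the argmax is the optimal subset size
  (ties prefer the smaller size); a feature's aggregate rank is the
  frequency with which it appears in the optimally-sized subset
  (per-size counting is a config switch). The round aggregation is
  essential: a single forest's importance ranking is noisy when
  hundreds of correlated nuisance descriptors surround weak signals,
  but features that persist across many resampled rounds accumulate
  frequency much faster than sporadically ranked noise.

  Importance is learner-appropriate. The random forest uses
  permutation importance — 100 × (error_permuted − error_baseline) /
  error_baseline with RMSE (regression) or 1 − AUC (classification) —
  computed on the training partition with a vectorised in-place column
  shuffle; scikit-learn's forests do not expose per-tree out-of-bag
  permutation importance, and an extra internal holdout would spend
  scarce training chemicals. The SVM has no native importance, so a
  filter metric is used per feature: the squared correlation between
  the response and a lowess smooth of the response on that feature
  (pseudo-R², lowess fraction 0.6), or for classification the
  single-feature AUC folded to max(AUC, 1 − AUC).

* **Ensemble.** `build_ensemble` trains members on random feature
  subsets (uniform, without replacement, from the selected pool) and
  random row subsets (⌈row_fraction × n⌉, default 0.8), and predicts
  with the unweighted member mean — a deliberate slight underfit that
  suits small assay datasets. Shuffled-label nulls (`fit_shuffled_null`)
  repeat the identical evaluation on permuted outcomes to establish
  the chance band.

* **Classification scores.** Forests emit vote fractions; the SVM
  emits a logistic map of its margin. Both are monotone ranking scores
  in [0, 1]; calibrated probabilities are not claimed (AUC, the metric
  used throughout, is invariant to monotone transforms).

## Percepts, screening, behavior

* **Percepts.** One independent regression model per odor descriptor
  maps structure descriptors to % usage on the 0–100 scale, clipped to
  [0, 100]. Exemplar descriptors are those with predicted usage
  *strictly above* 2× the descriptor's training mean (a prediction
  exactly at the threshold is excluded; the strict rule makes the
  degenerate all-zero column, whose threshold is 0, behave sensibly).
  Validation ranks all descriptors per chemical and computes ROC
  against an observed annotation set; chemicals with empty or full
  observed sets have no defined ROC and are flagged, not scored.

* **Screening.** Libraries are scored in row chunks (chunking is
  bit-identical to whole-matrix scoring), optionally rescaled to 100 ×
  score/score(reference chemical) — the "% repellency relative to
  DEET" presentation; the rescaling interpretation is optional because
  no formal definition of the relative scale exists. Nearest known
  repellents are found by Euclidean distance in the standardized
  training feature space. Filters are independent predicates
  (minimum score, required/forbidden percepts, maximum predicted Ca²⁺
  activity, excluded EPA toxicity categories — I and II by default),
  so the survivor set is order-invariant; missing filter inputs fail
  closed unless a lenient flag is set. Toxicity is consumed as an
  input column (category, or LD50 mapped at the standard oral
  breakpoints 50/500/5000 mg/kg) because the upstream toxicity model
  is external to this package. The Ca²⁺-activity cutoff is user-set;
  no principled default exists.

* **Behavior.** PI = (treated − control)/(treated + control); 0/0 is
  an error, never silently 0. The repellency coefficient summarises
  each trial as the *mean* of its cumulative landing counts over the
  2, 3, 4, 5 minute timepoints (the aggregation over the four counts
  is not dictated by the formula; the mean is the low-variance choice,
  and a final-timepoint mode is available), then averages trials per
  condition. Hill fits use four parameters with the lower asymptote
  free (baselines in luminescence assays are nonzero); a
  three-parameter mode pins it.

## Synthetic data: what it emulates, what it does not

No training corpus is redistributable (commercial descriptor engines,
a literature-curated chemical set, a copyrighted odor-percept atlas,
raw assay traces), so the package generates data with the structure
the analysis assumes:

* **Descriptors.** k informative features iid N(0,1); each of the
  p − k nuisance features is ρ·x_partner + √(1−ρ²)·ε for one randomly
  chosen informative partner, giving population correlation exactly ρ
  (default 0.3) — the simplest controllable stand-in for redundant
  descriptor families (autocorrelation series, fingerprint variants).
* **Response.** latent = Σ βᵢxᵢ + N(0, σ²), mapped affinely by its
  theoretical moments (mean → range midpoint, ±3 total SD → range
  edges) and clipped into [0, 100]. The map is monotone and
  sample-independent; clipping touches only the ~0.3% tail. The
  planted coefficient of determination is R² = ‖β‖²/(‖β‖² + σ²), and
  `noise_sd_for_r2` inverts it. Both a continuous-response and a
  binarized-label mode are provided, since curated training sets mix
  both.
* **Percepts.** Sparse % usage in [0, 100]: `sparsity` is the zero
  fraction (panelists use few descriptors per odorant); nonzero
  entries draw from a right-skewed Beta(1.5, 4) scaled to 0–100; every
  column keeps at least one nonzero entry because thresholding an
  all-zero column is undefined (sparsity = 1 is rejected).
* **Dose-response.** Replicates around a four-parameter Hill curve
  with iid Gaussian replicate noise.
* **Trap counts.** treated ~ Binomial(n, (1 + PI)/2), control = n −
  treated; full capture is assumed because the PI uses only trapped
  insects.

Each generator draws from its own counter-based substream of one
global seed (`SeedSequence(seed, spawn_key=(stream,))`), so adding a
generator never perturbs the others and identical configs are
bit-identical.

What the generators do **not** emulate: real descriptor distributions
(heavy tails, discreteness, block correlation across descriptor
families), nonlinear structure–activity relationships, panel-effect
correlations between odor descriptors, or plate effects in
luminescence data. Passing tests therefore demonstrate that the
machinery is correct and calibrated under its stated assumptions — not
that any particular real chemistry is predictable.

## Study conditions used by the acceptance computations

The geometry mirrors the study scale: **n = 201 chemicals, p = 500
descriptors, 18 informative features** with equal effect sizes.
Signal strength is set by the planted latent R²:

* *Moderate noise* (feature-recovery runs): R² = 0.8 — each
  informative feature then has marginal correlation ≈ 0.21 with the
  response, individually weak but jointly strong, which is exactly the
  regime where conditional selection (SFS, RFE round-aggregation)
  must outperform univariate screening.
* *Strong signal* (classification evaluation): R² = 0.98, chosen so
  that the generative ceiling — the ROC AUC of the noiseless signal
  against top-40% labels — is ≈ 0.994, the operating point the
  scaled-down evaluation is meant to emulate.
* *Regression regime*: R² = 0.6, whose oracle prediction ceiling is
  R = √0.6 ≈ 0.77, so a well-fitted model lands near R ≈ 0.7.

CV-RFE acceptance runs use k = 5 × 2 repeats (10 rounds per seed),
subset grid [500, 125, 62, 31], forests of 60 trees, and report the
median over 10 seeds; these sizes keep a full replicate under a minute
while leaving the round-aggregation enough rounds to stabilise the
frequency ranking.

## Numerical choices

* **Cleaning.** Order: high-missingness (> 20% by default) →
  near-zero-variance (caret-style frequency ratio, default 19) →
  pairwise |r| > cutoff, dropping the member with the higher mean
  absolute correlation (ties to the later name), then median
  imputation from the same (training) matrix. Cleaning is idempotent
  and order-preserving.
* **Standardization.** (x − mean)/SD per feature, with the statistics
  stored on the result; screening sets must be standardized against
  the training reference — never against themselves — for distances
  and kernels to live in one space.
* **Default grids.** SVM: cost ∈ {0.25, 1, 4, 16} × gamma ∈ (1/p) ·
  {0.1, 0.5, 1, 2}; forest: 500 trees, mtry ∈ {√p, p/3}. Chosen by
  inner CV when tuning is requested; all overridable.
* **Hill fitting.** Nonlinear least squares in log-EC50 space
  (positivity and conditioning), multi-started from the dose
  quartiles × slopes {0.5, 1, 2, 4, −1}; the best converged start by
  residual SS wins; a flat response returns a degenerate flag rather
  than a spurious EC50; top < bottom is canonicalised by mirroring the
  slope sign.
* **ROC.** scikit-learn curve points without intermediate dropping;
  trapezoidal area, which equals the tie-corrected Mann–Whitney
  statistic (asserted against an all-pairs oracle in the tests).
* **Quantile binarization.** Inclusive upper quantile; threshold ties
  all promote to active, and the achieved positive fraction is
  reported rather than re-split.
* **Ensemble archives.** A JSON manifest (member feature subsets, row
  subsets, seeds, hyperparameters) plus the training data as CSV;
  loading refits members deterministically from their recorded seeds.
  This keeps archives plain-text and diffable at the cost of a refit
  on load.
* **Determinism.** Every stochastic operation takes a seed;
  per-member/per-round seeds derive from one generator so reruns are
  bit-identical. Pipeline manifests hash the config (seed + stage
  parameters, not the output path) and record SHA-256 digests of every
  stage output.

## Known limitations

* The RF permutation importance inside CV-RFE is computed on the
  training partition; with heavily overfitted forests it can inflate
  nuisance-feature importance in any single round. The CV-RFE
  contract compensates by round aggregation, which is how the
  procedure is meant to be run; single-round rankings should not be
  trusted at n ≪ p.
* Per-descriptor percept models are independent; correlated descriptor
  usage (e.g. "fruity" co-occurring with "sweet") is not modelled.
* SVM classification scores are uncalibrated ranking scores.
* The descriptor backend contract assumes a fixed, named feature
  vector per SMILES; 3D-conformer-dependent descriptors are the
  backend's responsibility.
* `cv_rfe` recomputes importance at every elimination step, which is
  quadratic-ish in the subset grid; very dense grids on wide matrices
  are slow by design, not by accident.
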