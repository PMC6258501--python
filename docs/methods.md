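# Methods

## Problem setting

A child's short home video is tagged independently by several nonexpert
raters, each answering 30 multiple-choice behavioral items.  Answers map to
ordinal severity scores in {0,1,2,3} (higher = more severe autism-related
behavior) or 8 when a behavior cannot be scored from the video.  Eight named
classifiers — "model type"-"number of features" (ADTree7, ADTree8, SVM5,
LR5, LR9, SVM12, SVM10, LR10) — each consume a declared feature subset; the
union of the eight subsets has 23 distinct features and 7 further features
are tagged for the video-feature model only.  Classification is per rater,
then aggregated per video by majority rules.

The feature vocabulary is data, not code: `data/default_schema.yaml`
declares the 30 features, their answer→score maps and the per-model subsets.
Only the publicly named features carry real names; the rest are documented
placeholders, and all pipeline logic is schema-agnostic.  Subset *sizes*
(7, 8, 5, 5, 9, 12, 10, 10) and the 23-feature union are enforced
invariants; subset *composition* is configurable because the exact
feature-to-model incidence is not recoverable from public sources.

## Synthetic data generative model

No real rater data are available, so every stage runs on synthetic cohorts.

**Latent severity.**  Each feature f has a categorical distribution
p_un(s), s ∈ {0..3}, for the unaffected class (default
(0.55, 0.25, 0.12, 0.08)).  The affected class uses the exponential tilt
p_aff(s) ∝ p_un(s)·e^{γ_f s}.  A single knob γ ("severity shift", default
1.0, chosen so the suite lands in a realistic screening regime: sensitivity
high, specificity moderate, AUC ~0.9) guarantees first-order stochastic
dominance of affected scores for every γ ≥ 0.  Per-feature γ_f supports
planted-signal cohorts (only chosen features informative) for
parameter-recovery tests.

**Score sheets.**  Training cohorts are noiseless per-child draws from the
class-conditional distributions, at the per-model archive sizes (e.g. 1,319
affected / 70 unaffected for the 5-feature models; 612/15 for the 8-feature
tree), so each model inherits its original imbalance regime.

**Rater noise.**  All raters of a video share its latent scores; each rater
observes them through a symmetric adjacent-category confusion kernel: with
probability ε the recorded level moves to a neighboring severity level (mass
split equally between the two neighbors, reflected at the boundary), and
independently each cell becomes the unscorable code 8 with probability
`missing_rate` (default 0.02).  Errors are independent across features and
raters; real rater errors are plausibly feature- and rater-correlated —
that correlation is deliberately not modeled.

**Calibration.**  ε is not set directly but calibrated: bisection on ε until
the Monte-Carlo frequency with which all 3 raters' model classes coincide
(averaged over 5 replicate 162-video cohorts) matches a target interrater
agreement, default 0.72 under the 5-feature logistic model, matching the
observed unanimity level.  Unattainable targets (outside the achievable
range at ε ∈ [0, 0.9]) raise a calibration error reporting that range.

**Ages** are per-class truncated normals on the eligibility window
[1, 17] years (affected 4.83 ± 2.25, unaffected 2.92 ± 1.17 years); the four
evaluation bins are ≤2, (2,4], (4,6], >6 years, left-open right-closed.

What passing tests show — and do not show: the pipeline's logic, statistics
and resampling procedures are correct under a stylized independent-noise
generative model at the study's cohort sizes.  They say nothing about how
real nonexpert raters behave, and headline real-data accuracies (AUC 92% on
162 videos; 93.3% held-out for the elastic-net model) are out of
reproduction scope because the underlying data and original model weights do
not exist publicly.

## Classifier suite

* **Logistic models** (LR5/LR9/LR10): scikit-learn logistic regression on
  standardized scores, penalty L1 by default (an L2 toggle exists for the
  5-feature model, whose penalty is reported inconsistently in public
  sources), inverse-class-size weights, C tuned on a small grid by
  cross-validated AUC.
* **Linear SVMs** (SVM5 L1, SVM10 L2): squared-hinge LinearSVC;
  probabilities via a Platt-style logistic link fit on the training margins
  (own fit on the 1-D margin, so serialization is exact).
* **RBF SVM** (SVM12): SVC with gamma="scale"; same Platt-style link; the
  serialized model stores support vectors, dual coefficients, gamma and
  intercept and evaluates the kernel expansion directly.
* **Alternating decision trees** (ADTree7/8): own implementation.  Margin =
  root prediction + the prediction value of every branch reached; training
  adds one splitter per boosting round under an existing prediction node,
  minimizing the Z-criterion over all (node, feature, threshold) candidates;
  ordinal scores admit only thresholds {0.5, 1.5, 2.5}.  Prediction values
  are smoothed half-log-odds (ε = 1e-8); weights update by e^{−y·a}, so the
  weighted loss is non-increasing.  Rounds stop when the distinct-feature
  count reaches the target or no candidate reduces the loss (cap: 4× the
  target).  Probability link: σ(2·margin), the boosting-margin logistic.
  Class imbalance: boosting plus optional seeded minority up-sampling to
  parity (a single up-sampled set; a 1,000-member resampling ensemble is not
  re-trained — it served as a sensitivity check, not a deployed model).
* **Backward elimination**: iterative removal of the single lowest-ranked
  feature, rank = mean |standardized L2-logistic coefficient| across
  stratified CV folds (the original ranking statistic is unstated; this is
  the package's choice).  Exact ties remove the first lowest feature, so a
  constant feature is removed first, deterministically.
* **Missing code 8**: must be imputed before scoring.  Policies: `zero`,
  `feature_mode_from_training` (default — per-feature training-set mode;
  least-information choice that keeps all raters), `drop_rater`.  An all-8
  record is unusable under the mode policy and is dropped from consensus.
* Ties at probability exactly 0.5 classify as affected: in screening, the
  cost asymmetry favors sensitivity.

## Consensus, sufficiency, triage

Votes: strict majority for odd rater counts; exactly two raters must agree;
an even split is broken by one vote drawn uniformly from the reserve pool
(usable raters of the video outside the voting subset — never a re-used
voter; an empty reserve is an error, not a silent fallback).  The pooled
per-video probability is the arithmetic mean of rater probabilities
(median available; the original pooling rule is unstated).

The rater-sufficiency bootstrap draws rater *identities* with replacement
(1,000 trials per k, k = 1..9 by default) and re-uses each drawn rater's
recorded tags; duplicate draws contribute duplicate votes.  A consequence
worth knowing: with a 9-rater pool, ~31% of k = 3 draws contain a duplicate,
collapsing the majority onto a single rater, so the mean accuracy at k = 3
sits between the single-rater accuracy and the independent-triplet
closed form q³ + 3q²(1−q); the closed form is recovered when the pool is
large (duplicates rare), which is how the package's closed-form check is
run.  The 3-vs-9 comparison uses a percentile bootstrap (2,000 resamples) on
the per-draw accuracy distributions; because all draws share one cohort,
this CI reflects resampling noise only, and with a sensitivity-heavy tree
model the accuracy-vs-k curve is nearly flat — a statistically "nonzero"
difference of a few thousandths should be read against the per-draw SD, as
the analysis driver does.

Triage: pooled probability in [band_low, band_high] = [0.4, 0.6], boundaries
inclusive by default (inclusivity is unstated in public sources and is
configurable), flags a video inconclusive; metrics are recomputed on the
conclusive subset.  Triage never alters conclusive classifications, only
membership.

Metrics with an empty denominator (e.g. specificity in an age stratum with
no unaffected children) are NaN with a warning, never silently 0.  AUC is
the rank (Mann–Whitney) construction with a stratified percentile-bootstrap
95% CI (2,000 resamples by default).

## Elastic-net video-feature model

Unit of analysis is the pooled rater row (three rows per video, 176 videos /
528 rows in the default run), but split integrity is enforced at the video
level: a video's rows never straddle the 80/20 split, and each class's video
count is stratified exactly; evaluation on any training video raises a
leakage error.  `alpha` is the per-sample penalty weight (scikit-learn
`C = 1/(alpha·n)`) on standardized scores; the grid (alpha ∈ {0.001, 0.01,
0.1, 1}, l1_ratio ∈ {0.2, 0.6, 1}) is searched with video-grouped CV folds,
maximizing AUC with accuracy and then higher l1_ratio (sparser) as
tie-breaks.  On synthetic data this AUC-first rule often prefers dense
models; sparsity behavior is instead exercised by planted-support recovery
tests (L1 logistic recovers ≥4/5 planted features in ≥80% of 50 seeds; the
elastic-net grid recovers ≥6/8 in ≥80% of 25 seeds).

## Determinism and numerics

Every stage consumes a seed derived deterministically from one master seed
(`child = (master·10007 + 31·idx + 1) mod 2³¹`); identical config + seed
reproduces all tables byte for byte, and the manifest records the config
hash, seed, noise level and row counts.  Saga elastic-net fits use tol 1e-4
(tightened in tests that compare against unpenalized optima); non-converged
fits raise rather than return silently.  Standardization guards zero-variance
features by unit scale.  Test problem sizes (e.g. 400-sheet training
cohorts, 160-video recovery cohorts, 3-fold CV inside grid-search recovery
loops) are the package's default desk-scale settings; the full study-sized
run is exercised by the analysis drivers and the acceptance script.

## Known limitations

* Independent, symmetric, feature-homogeneous rater noise; no rater-specific
  bias or feature correlation.
* The default schema's feature subsets are a documented stand-in for the
  unpublished incidence matrix; only sizes and union cardinality are
  enforceable.
* Original trained weights are unrecoverable; all performance numbers are
  properties of the synthetic conditions, not reproductions of the study's
  real-data accuracies.
* The post-triage sensitivity/specificity pair reported for the original
  validation set cannot be reconstructed from printed counts (the class
  composition of its inconclusive videos was not published) and is treated
  as non-reproducible.
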