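# Methods

## Problem and model

`bndecode` decodes which of several stimulus classes (e.g. hand-written
digits 0–9) evoked a multivoxel fMRI response pattern. The input to
decoding is a trial-by-voxel matrix of GLM contrast t-statistics, one row
per stimulus presentation, with per-voxel anatomy (MNI coordinate,
Brodmann area, lobe).

The classifiers are Bayesian networks over the class node C and the
selected voxels A_1…A_n. C has no parents and is a parent of every
attribute, so the joint factorizes as

    P(C, A_1, …, A_n) = P(C) · Π_i P(A_i | Π_i, C),

where Π_i is the set of attribute parents of A_i. Naive Bayes is the
special case Π_i = ∅. The augmented naive Bayes (ANB) classifier learns a
shared set of attribute→attribute edges from the training data and reads
them as effective connectivity: the influence voxels exert on one another
beyond what the stimulus class explains. Classification picks
argmax_c P(c | a), computed in the log domain with log-sum-exp
normalization so that products over hundreds of voxels never underflow;
posterior ties break to the smallest class label (measure-zero in the
continuous model).

### Conditional distributions

How continuous t-values enter the conditionals is an open design choice;
the default is **class-conditional linear Gaussians**: for each class c,

    A_i | Π_i = π, C = c  ~  N(b_ic + w_ic·π, σ²_ic),

fitted per class by least squares with MLE (divide-by-n) residual
variance, floored at 1e-8 to survive exactly collinear degenerate inputs.
This keeps the data continuous and the factorization exact. An
alternative **discrete mode** (equal-frequency binning, default 4 bins,
pure-MLE CPTs with zero cells floored at 1e-12 at prediction time, and an
optional pseudo-count) is provided for users who prefer contingency-table
CPDs; both paths share the same structure-search and prediction code.

### Structure learning

Augmenting edges are found by greedy hill climbing on BIC:

* score of a family = maximized log-likelihood − (ln N / 2) × free
  parameters; a linear-Gaussian family with p attribute parents costs
  C·(p + 2) parameters (intercept, weights, variance per class);
* search starts from the naive Bayes skeleton (empty attribute-edge set)
  and at each step applies the best single **insertion, deletion, or
  reversal** of an attribute edge; class edges are immutable;
* the score is decomposable, so a move rescores only the families it
  touches; family scores are computed from per-class Gram matrices in
  O(p³), independent of trial count, and memoized;
* the search stops when no move improves the score by more than 1e-9, or
  after `max_steps` (default 10 × attribute count — the stopping rule's
  step budget is otherwise unspecified, and this bound is never reached
  in practice on the scales used here);
* ties between equal-scoring moves break canonically (add < delete <
  reverse, then parent id, then child id), making the search fully
  deterministic; the `seed` argument is accepted for interface stability
  but unused;
* `max_parents` defaults to 3 attribute parents, bounding parameter
  count at the ~100-trials-per-class scale;
* acyclicity is enforced incrementally (descendant checks before each
  insertion/reversal).

One shared edge set is learned across classes while parameters remain
per-class: the augmentation is a single structure added to the naive
Bayes skeleton, not a per-class graph.

## Evaluation protocol

* **Stratified k-fold CV** (default k = 10): each class is shuffled by
  seed and dealt round-robin, so folds carry equal class counts (±1 when
  not divisible). The same folds serve every classifier and sweep point.
* **Fisher-score voxel selection** computed on training trials only:
  f_i = Σ_j n_j (μ_ij − μ_i)² / Σ_j n_j σ²_ij with population (divide-by-
  n_j) within-class variances — the Duda-style criterion; `ddof=1` is
  available. The denominator is floored at 1e-12; constant features
  score 0. Top-k selection breaks score ties by ascending voxel id.
* **Voxel-count sweep**: default 50–550 in steps of 50 (11 points; the
  range is standard for this protocol, the step a granularity choice).
* **KS comparisons**: two-sample Kolmogorov–Smirnov test at α = 0.01 on
  per-fold accuracy samples; pooling across the sweep is available where
  a single sweep point gives too few observations.
* **Chance level** = 1 / n_classes (10% for ten balanced classes); a
  label-permutation routine re-runs the entire fold/selection/fit
  protocol on permuted labels to calibrate it empirically.
* **Common voxels**: selected in ≥ 6 of 10 folds ("more than five").

## Connectivity and similarity summaries

* BA contribution = per-fold percentage of selected voxels in each area,
  averaged over folds (not over pooled unique voxels); areas above 15%
  are flagged.
* Edge BA-pair frequencies discard direction (pairs are unordered;
  within-area pairs counted) and flag pairs strictly above 5% of pooled
  edges. Raw edge exports keep direction.
* Edge length distribution: Euclidean endpoint distance in mm, 10 mm
  half-open bins over 0–80 mm (final bin closed) plus an overflow bin.
* Similarity analysis averages active voxels per BA into one response
  vector per area (active = union of voxels selected in any fold, unless
  an explicit mask is given), takes correlation distance 1 − Pearson r
  (Spearman would be a defensible alternative; Pearson is the
  convention), clusters by complete linkage (furthest distance), and
  cuts at strictly less than half of the maximum pairwise distance.
  The agglomeration is implemented in-package so ties resolve
  deterministically (lexicographically smallest leaf labels); scipy's
  complete linkage is used as an independent cross-check in the tests.

## GLM response estimation

`build_design_matrix` makes one task regressor per stimulus event
(boxcar of the event duration convolved with the canonical double-gamma
HRF — SPM-convention delays 6 s / 16 s, undershoot ratio 1/6 — sampled
at the TR), appends nuisance columns, cosine drift regressors
implementing a 100 s high-pass, and an intercept. `fit_glm_tstats` is
plain OLS per voxel with t = c′β̂ / √(c′(X′X)⁻¹c·σ̂²), σ̂² = RSS/(n −
rank). Prewhitening is deliberately omitted: it is estimator plumbing
orthogonal to the decoding method, and the synthetic noise here is
white. Fits are intended per run; pooled t-values are used raw, without
cross-run variance normalization (flagged assumption). Zero-residual
voxels get t = sign(c′β̂)·1e6 rather than ±∞. Rank-deficient designs
raise, naming the collinear columns.

## Synthetic data generator

The generator emulates the statistical structure the decoder exploits,
at the study's stated conditions: 10 balanced classes × 100 trials,
a few hundred voxels with 2.2 mm grid spacing grouped into contiguous
Brodmann-area blocks (blocks separated by centimetres, as distinct areas
are), per-(class, voxel) mean responses drawn N(0, 1) against unit
trial noise, and a planted sparse DAG of linear couplings (default
weight 1.5) whose edges are sampled with probability ∝ exp(−d/5 mm), so
connectivity is spatially local and the short-edge finding is a
recoverable property. The planted DAG caps in-degree at 1 (chains and
pairs): this keeps the generating family free of v-structures, so the
adjacency set is identifiable and recovery can be scored cleanly.
Edge weights may be per-class; the coupling-contrast dataset uses
weights ±w with zero means so the two classes have identical marginals
and differ only in dependency sign — a regime where naive Bayes is
provably at chance and any advantage must come from the learned edges.

BOLD simulation is a sum of amplitude-scaled HRF-convolved boxcars plus
white noise. The generator does **not** model spatial autocorrelation,
physiological confounds, scanner drift beyond what the drift regressors
remove, or image-domain artefacts — so passing tests demonstrate the
estimators and classifiers behave correctly under the assumed model, not
that real fMRI satisfies those assumptions.

A single master seed feeds `numpy.random.default_rng` substreams per
stage, so every artefact is bit-reproducible from (config, seed); the
CLI's `all` command re-run with one seed produces byte-identical tables.

## Problem sizes used in the checks

The shipped checks run at desk scale: chance-level calibration uses the
full 10×100-trial dataset with 200 voxels and 200 permutation
replicates; structure recovery uses 12–30 voxels at 2000 trials;
parameter recovery uses 5000 trials per class on a 3-voxel chain; the
coupling-contrast comparison uses 8 voxels × 1000 trials with 10-fold
CV. These sizes make each property sharp while keeping a full run of the
suite in the low minutes.

## Known limitations

* Subject-level results from real acquisitions (specific BA tables,
  accuracy curves, the 12-cluster partition) depend on data that is not
  redistributable; the package reproduces the *procedures* and verifies
  them on synthetic ground truth.
* Hill climbing is a local search; with strongly dependent chains it can
  return score-equivalent orientations, which is why recovery is scored
  at the adjacency level.
* The linear-Gaussian CPDs assume homoscedastic within-class noise;
  heavy-tailed voxels would argue for the discrete mode.
* OLS t-statistics without prewhitening are slightly anticonservative
  under temporally autocorrelated noise.
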