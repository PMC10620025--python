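# Methods

`dtwfc` implements a pipeline for asking whether dynamic-time-warping (DTW)
functional connectivity carries more diagnostic information than the standard
Pearson-correlation (PC) connectivity when region-pair similarities feed a
binary classifier, and for quantifying how the choice of cross-validation
(CV) protocol biases the reported accuracy. This note records the models,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic generator does and does not emulate.

## Connectivity measures

A subject is an ROI × time matrix `X ∈ R^{R×T}` sampled at interval `dt`
seconds (the scanner's repetition time). Pearson connectivity between
regions i and j is the ordinary correlation `r_ij` of their series; it is
exact zero-lag coactivation and is attenuated whenever one region's response
leads or lags the other.

DTW connectivity is the minimum cumulative pointwise cost over monotone
alignments of the two series. With local cost `c(u, v) = |u − v|` and the
unweighted three-predecessor recursion

    D(i, j) = c(x_i, y_j) + min{ D(i−1, j), D(i, j−1), D(i−1, j−1) },

the DTW distance is `D(T−1, T−1)`. A Sakoe–Chiba band `|i − j| ≤ w`
restricts how far alignment may deviate from the diagonal; the band
half-width is specified as a warping window in seconds and converted by
`w = floor(window / dt)`, so the default 100 s window at `dt = 2 s` gives
`w = 50` samples. Squared local cost is available; absolute cost is the
default. The step pattern is exposed as a parameter but only the unweighted
symmetric recursion is implemented: it is the textbook dynamic program that
the banded cumulative-cost construction assumes, and the brute-force
path-enumeration oracle in the test suite is the authority that the
recursion is solved exactly.

Backtracking recovers one optimal path with a deterministic tie rule
(diagonal, then vertical, then horizontal); the distance is tie-invariant.
Out-of-band cells carry `+inf` sentinels, which keeps the recursion
branch-free; an unequal-length pair whose length difference exceeds the band
has no admissible path and raises an explicit error.

Region series are z-scored (population standard deviation) before DTW by
default. DTW on raw amplitudes conflates scale with shape — two perfectly
synchronized signals of different amplitude would register a large distance
— whereas the scientific target is shape similarity; PC is scale-invariant
and unaffected. A raw mode is available for sensitivity analyses.

## Features and the similarity transform

The strict upper triangle of the symmetric R × R connectivity matrix, in
row-major order, is the subject's feature vector: `P = R(R−1)/2` features
(105 regions → 5460). The feature order and the `ROIi__ROIj` naming are part
of the file contract; a hash of the name sequence is written to every
sidecar.

DTW distances become similarity features by negation followed by per-feature
demeaning. Negation makes larger values mean "more similar" (a strictly
decreasing transform); demeaning centers each region-pair column. Centering
is a *fitted* transform: computing column means on the full sample lets
held-out subjects influence the training representation. The default mode
therefore treats demeaning as part of the model pipeline — means are
computed on each CV training block and applied to its held-out block
(`SimilarityDemeaner`, a scikit-learn transformer). A `global` mode that
demeans over the whole sample before CV is provided for comparison with
analyses that applied the transform upstream; for SVM margins and PCA the
two differ only through the leakage, which is precisely what the default
avoids.

## Classifiers

Four classifiers are compared, all instantiated from scikit-learn behind a
thin adapter layer: linear-kernel SVM, radial-kernel SVM, L1-regularized
linear SVM (squared hinge, liblinear), and random forest. The random forest
is fixed a priori — 500 trees, `floor(sqrt(P))` candidate features per
split — and has no tuned hyperparameters. The SVMs draw hyperparameters by
random search: the misclassification penalty `C` log-uniform on
[1e−3, 1e3], and for the radial kernel additionally the inverse squared
length scale `gamma` log-uniform on [1e−4, 1e1]. These ranges are this
package's own choices (several decades around the library defaults); they
are echoed into every results file, and the radial width is reported in both
the `gamma` and the equivalent kernel-library `sigma` convention to avoid
ambiguity. Decision thresholds are the library defaults (zero margin,
majority vote); no probability calibration is applied.

A practical note on the L1 model: the classical result that an L1 penalty
keeps at most `min(n, P)` features active is a property of
linear-programming/Lasso solution vertices. The squared-hinge coordinate
descent solver can exceed that count slightly at weak regularization; the
test suite asserts the strict bound in the regularized regime and a
far-below-P active set elsewhere.

## Cross-validation protocols

* **Repeated nested K-fold CV** (default 5 outer × 5 inner folds, 80 random
  search iterations at full scale). Outer folds estimate performance; for
  each outer training block, an inner K-fold CV scores each candidate by
  pooled inner accuracy and the winner is refit on the whole block. Metrics
  are computed from the pooled outer predictions of each repeat and averaged
  over repeats (100 at full scale).
* **Nested LOOCV** (inner 3-fold, 40 search iterations): the outer loop
  leaves one subject out; metrics come from the pooled n predictions, since
  per-singleton rates are undefined.
* **Optimistically biased CV** (10-fold, 80 candidates): one plain K-fold CV
  per candidate — the same fold split for every candidate, isolating the
  selection effect from fold noise — and the maximum candidate accuracy is
  reported. This is the estimator whose upward bias the nested protocols
  remove: the same held-out data selects the hyperparameters and scores
  them.
* **Plain repeated K-fold** (15-fold, 100 repeats at full scale) for the
  untuned random forest.

Folds are stratified by class (outer and inner); with roughly 100 subjects
and K = 5, unstratified folds risk class-imbalanced or single-class
training blocks. When a class has fewer members than K — always the case
for leave-one-out — fold construction downgrades to unstratified with a
warning. Inner selection uses pooled inner accuracy; ties prefer the
smaller penalty `C`, then draw order, making selection deterministic and
biased toward simpler models.

All fitted preprocessing (PCA, similarity demeaning) lives inside a
scikit-learn `Pipeline` refit on every training block. PCA requests are
capped at the achievable rank of the centered training block — a request
beyond rank truncates with a warning rather than erroring, since a
79-subject training block supports at most 78 components regardless of the
requested width. The default when PCA is enabled is 30 components.

Randomness follows a seed ladder: one master seed per protocol derives
per-repeat, per-fold and per-candidate child seeds through
`SeedSequence([master, *indices])`. Any single fold or candidate draw is
reproducible in isolation, and two measures evaluated under the same
protocol seed see identical fold assignments, making measure comparisons
paired.

## Synthetic generator

The generator stands in for a restricted clinical sample; it emulates the
*structure* of a two-group resting-state study, not any particular cohort.
Defaults: 20 subjects per group, 20 regions, 180 time points at `dt = 2 s`,
AR(1) background sources with coefficient ρ = 0.3 (unit marginal variance),
5 shared latent sources with Gaussian loadings of scale 0.5 drawn once per
study, white measurement noise of unit standard deviation, and per-region
z-scoring. The desk-scale geometry (20×20×180) keeps a full
measure-comparison run in minutes; sample size and region count scale up by
config.

Group differences enter through informative pairs, designed so that the two
groups are *variance-matched*: every subject receives extra fluctuations of
equal amplitude (default 2.0) in both regions of the pair, and the groups
differ only in whether those fluctuations are shared. In group B they are a
single common source; in group A they are independent sources. A
`strength` pair injects the common source synchronously — visible to both
PC (correlation rises) and DTW (distance falls). A `lag` pair delays the
common source's copy in the second region by τ samples (circular shift,
default 1 sample = 2 s, within the ±2 s range of inter-regional
hemodynamic delays). The injected pair sources are temporally white at the
sampling resolution, so a one-sample lag removes their zero-lag correlation
entirely: the lagged coupling is invisible to PC but remains visible to
DTW, which realigns the two series inside its band. Variance matching is
essential — injecting extra variance into one group only would leak an
amplitude signature through z-scoring into every pair touching the coupled
regions, a side channel a correlation-based classifier exploits immediately
(verified during design: without matching, PC classifiers win on pure
amplitude, regardless of the lag structure).

The default pair amplitude 2.0 makes a single informative pair clearly
learnable at n = 40 subjects with 190 features; the resulting DTW-side
accuracies (≈0.7–0.85) are of the order reported in real connectivity
classification studies, while PC on a lag pair stays at chance.

Circular shifts (rather than truncation) keep series length and
stationarity; edge wraparound changes DTW distances slightly, which is one
reason the brute-force oracle, not an analytic formula, anchors the DTW
tests. An optional canonical double-gamma hemodynamic-response convolution
(peak 6 s, undershoot 16 s, ratio 1/6, 32 s support) is available as a
robustness knob; it is **off** by default because its low-pass character
partially re-synchronizes lagged sources and thereby weakens the very
mechanism the lag pairs exist to express.

What the generator does *not* emulate: vascular and physiological noise,
motion artifacts, scanner drift, multi-site effects, spatially structured
parcel geometry, and heterogeneous per-subject hemodynamics. Passing tests
on this generator demonstrate that the pipeline detects the intended
coupling structures and that the protocols are calibrated and leakage-free;
they do not certify accuracy levels on real clinical data.

A separate helper draws pure-noise feature tables (i.i.d. standard normal
features, balanced labels independent of features) whose true accuracy is
0.5 by construction — the known-truth input for the CV-bias study.

## The CV-bias study

For each replicate, a fresh known-truth dataset is drawn and estimated by
nested 5-fold CV, optionally nested LOOCV, and optimistically biased 10-fold
CV under a shared master seed. The reported quantities are per-protocol
means, standard deviations, and mean pairwise gaps. The default model is
the radial SVM: max-selection bias feeds on candidate-to-candidate variance
of the CV score, and the radial kernel's two-dimensional search space
supplies it. The linear SVM on high-dimensional data is nearly invariant to
its penalty — candidates collapse to the same separating hyperplane — so it
shows little or no optimism and makes an uninformative default (this
exception is itself reproduced by the pipeline).

A subtlety worth recording: CV estimates on a *single* finite null dataset
scatter widely (roughly 0.35–0.68 at n = 60, p = 300) because a finite
sample contains accidental label/feature structure that fold reshuffling
cannot average away. Calibration statements in the tests therefore average
over independent dataset draws, which targets the procedure's unconditional
bias; with class-balanced stratified folds that unconditional mean is
exactly 0.5.

## Numerical conventions and degenerate inputs

* z-scoring uses the population (divide-by-n) standard deviation; a
  constant region series raises an error naming the ROI.
* DTW requires series of length ≥ 2 with finite values; the empty and
  single-point cases error.
* Band infeasibility (unequal lengths beyond the band) raises rather than
  returning a sentinel.
* Connectivity matrices are validated symmetric to 1e−8 before
  vectorization; diagonals (1 for PC, 0 for DTW) are never exported as
  features.
* Metrics: sensitivity is the true-positive rate of the case class (label
  1), specificity the true-negative rate of controls; a class absent from
  the truth vector yields NaN for its rate while accuracy remains defined.
  Pooled results satisfy `acc = (sens·n₊ + spec·n₋)/n` exactly.
* Single-class training folds raise a degenerate-fold error; stratification
  prevents them in supported designs.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full protocols at
reduced budgets chosen so a complete run takes minutes on one core: nested
CV with 10–20 random-search iterations and 1–2 repeats, 10–25 replicates
for direction checks, and desk-scale synthetic studies (40 subjects, 20
regions). The protocol structure — nesting, stratification, in-fold
preprocessing, seed ladders — is identical at every scale; only repeat and
search counts shrink. Full-scale budgets (100 repeats, 80 iterations)
remain available through the protocol objects.

## Known limitations

* Only the unweighted symmetric DTW step pattern is implemented; weighted
  patterns and endpoint relaxations are out of scope.
* The L1 active-set bound is asserted only in the regularized regime (see
  above).
* Nested LOOCV reports a single pooled estimate; replicate spread across
  seeds, not per-run error bars, is the dispersion measure offered.
* The generator's group effects are stylized (white shared sources,
  circular lags); effect sizes are calibrated for desk-scale detectability,
  not estimated from data.
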