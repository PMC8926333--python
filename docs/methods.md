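# Methods

This note documents the models, procedures and design choices behind
`fairconn`: what the synthetic generator emulates, how the matched designs
are built, the exact metric and inference definitions, and the numerical
conventions. It is the place to look when a default needs justification.

## Synthetic generative model

The generator (`fairconn.synthetic`) emulates the statistical structure a
cross-population prediction audit assumes of its inputs, not the biophysics
of fMRI.

**FC features.** Each subject's vectorized Fisher-z FC is drawn from a
shared latent low-rank-plus-diagonal Gaussian,
`c = mu + B u + sqrt(d) eps + L f`, with `B` a p×k loading matrix
(`latent_rank` k = 10, loadings N(0, 0.05²)), diagonal variance
`d = 0.01`, edge means N(0.1, 0.05²) — giving per-edge z values of
realistic scale (sd ≈ 0.19 around a small positive mean). `L` carries the
confound edge loadings. Group differences deliberately do **not** enter the
FC distribution itself: they live in the weight patterns, the behavioral
mean shift, the variance ratio, and the confound loadings. This isolates
the bias mechanism under study (association-pattern divergence) from
nuisance covariate shift, which the confound loadings can re-introduce in a
controlled dose.

**Behavior.** `y = c·w_group + beta·f + shift·1[minority] + noise`. The two
unit-norm, zero-mean weight vectors are constructed so their Pearson
correlation equals `pattern_similarity` exactly (Gram–Schmidt on centered
Gaussian vectors). The "other" group uses the majority pattern. The default
noise (`noise_sd=None`) sets the majority noise SD to the realized signal
SD, i.e. population R² = 0.5 — a deliberately optimistic but attainable
signal level for connectome-based prediction. Minority noise is then
rescaled so Var(y_min)/Var(y_maj) hits `group_variance_ratio` exactly in
population; when `noise_sd=0` both groups get zero noise and the noiseless
identity `y = c·w` takes precedence over variance targeting (the two
requirements conflict when the two patterns' signal variances differ
slightly).

**Confounds.** Age-like and motion-like continuous variables (standard
normal) and a gender-like Bernoulli(½); each loads linearly on `y` and on a
seeded random 10% subset of edges. Confound covariance is diagonal, so the
population edge–behavior covariance has the closed form
`Sigma_0 w + L Sigma_f L' w + L Sigma_f beta` used as the ground-truth
association oracle.

**Structure.** Family sizes are drawn from {1: 0.6, 2: 0.3, 3: 0.1}
(twin/sibling-cohort-like); families are group-homogeneous and sit wholly
inside one site, so family blocks never straddle sites.

**Time series.** For QC testing the generator emits per-run Gaussian ROI
series whose sampling correlation is the subject's FC mapped to correlation
space and projected to the nearest positive-definite correlation matrix
(eigenvalue clipping, diagonal rescale); FD/DVARS traces get spike frames
at a configurable rate. The generator does **not** emulate hemodynamics,
autocorrelation, parcellation geometry, scanner effects, or realistic
missingness — so passing tests show the *pipeline machinery* behaves
correctly under the assumed statistical structure, not that real HCP/ABCD
data satisfy that structure.

All randomness derives from one integer seed via fixed stream offsets
(`default_rng([seed, stream, ...])`); datasets are bit-reproducible.

## Frame censoring and RSFC

Frames with FD or DVARS above threshold are censored, the flag is dilated
one frame back and two forward, surviving uncensored segments shorter than
five contiguous frames are censored too, and a run is discarded when
*strictly more than* half its frames are censored (exactly half survives).
Presets: 0.2 mm / 75 (single-site-like) and 0.3 mm / 50 (multi-site-like).
DVARS is the RMS of the frame-differenced signal with frame 0 assigned 0 so
it can never censor itself. RSFC is the Pearson correlation over uncensored
frames per run, clipped to ±(1 − 1e−7) before `atanh` (degenerate r = ±1 is
otherwise infinite), averaged in z across usable runs, unweighted by frame
count (a weighted variant is a flagged switch). Edge vectorization is
strict-lower-triangular in column-major order; every FC file's JSON sidecar
records this ordering. Segments are defined within a run only.

## Matched designs

The pair cost is the sum of absolute differences over the cost variables,
each z-scored over the union of the two groups (raw sums across
incommensurate units would let one variable dominate); gender is an
exact-match constraint via a large sentinel cost rather than a 0/1 numeric
difference. Hungarian assignment (`scipy.optimize.linear_sum_assignment`)
gives the minimum-total-cost injective pairing.

**Single-site scheme.** A hard-to-match pre-pass excludes minority subjects
whose minimal attainable pair cost exceeds the 90th percentile of minimal
costs in ≥ 80% of behaviors (both thresholds configurable). Remaining
minority subjects are randomly split into family-preserving folds; over
`n_iter` random majority draws the Hungarian matching runs and the draw
with the lowest maximal per-fold cost wins; the whole procedure repeats for
`n_splits` independent splits, and everyone unmatched is distributed into
the folds with families intact. Three feasibility refinements were needed
where the procedure is otherwise underdetermined:

* draws are stratified over the categorical cells (per-gender counts equal
  to the minority's) — an unstratified equal-size draw must hit those
  counts exactly by chance, making almost every draw infeasible;
* the Hungarian assignment runs globally over the draw, each matched
  majority subject inheriting its minority partner's fold (the partition of
  a draw into folds is otherwise arbitrary and random chunking is
  infeasible under the gender constraint);
* at most one member per majority family is drawn, since two matched
  same-family subjects would usually land in different folds, violating the
  family-intact constraint; unmatched relatives of a matched subject are
  later pinned to that subject's fold.

**Multi-site scheme.** Within each site, iterative matching: match all
remaining minority, drop the unmatchable ones and the single highest-cost
minority, stop after 100 rounds or when the cost decrease falls below 5% of
the previous round. A lone matched pair is kept rather than dropped (the
mandatory drop would otherwise annihilate single-pair sites). Sites are
then merged into folds by a documented greedy rule — largest site into the
currently smallest fold, ties by id — and every 7-train/3-test fold
combination (C(10,3) = 120) forms one split, never averaged.

**Validation.** Paired t tests on matched differences per variable,
Benjamini–Hochberg FDR over the supplied family; zero-variance differences
report t = 0, p = 1 with a warning. Residual imbalance can survive even
optimal matching when a realized sample carries a chance group shift in a
confound; the analysis drivers report such flags instead of suppressing
them, and the matched-audit answer is to drop the affected behaviors.

## Prediction

Kernel ridge regression with the correlation kernel is the primary model;
linear ridge on the edge features is the auxiliary (and equals kernel ridge
with the linear kernel at matched λ — a cross-implementation test). The
penalty is selected by inner cross-validation grouped by family (or site),
scoring pooled inner-validation predictions by predictive COD
(correlation is a config switch), ties to the smallest λ. The default grid
is 15 log-spaced values in [1e−3, 1e3] scaled by training size; replicate
studies use a fixed 5-point grid (1e−2 … 1e2) for speed. Confound
regression is strictly fit-on-train/apply-to-test; a tripwire test verifies
that a confound predictive of test scores only cannot inflate accuracy.

Training-population arms: `minority_only` takes all training minority;
`majority_only` takes an equal-count per-site random majority sample
(sites with fewer majority than minority trim random minority down to the
majority count first); `balanced` is their union. The pooled SST used for
COD is computed from the matched training subjects of the two compared
groups regardless of the arm, so arms are scored against the same
denominator.

## Inference

P-values use the add-one estimator, `p = (1 + #{null ≥ obs}) / (1 + n_perm)`,
one-sided for predictability, two-sided (symmetric tails) for differences;
n_perm defaults to 1000. The block permutation groups subjects into
exchangeability blocks (families): whole blocks permute only among
same-size blocks and orderings shuffle within blocks; all-singleton blocks
reduce to an ordinary permutation. The flip-label test swaps each matched
pair's labels independently with probability ½ (a global reshuffle is
available behind a flag). FDR control is Benjamini–Hochberg throughout. A
behavior counts as predictable when its whole-test-set accuracy survives
the FDR-corrected block permutation *and* its mean split accuracy is
positive in at least one matched group; the headline subset further
requires mean r strictly above 0.15.

## Association patterns

The model-learned map is `cov(FC_edge, y_hat_train)` with population
denominator and both arguments demeaned; for linear ridge it equals
`Sigma_train w` exactly (tested). True group maps use matched test
subjects only. Similarities are Pearson correlations across edges. For the
pattern-validity study, maps are computed per split and **averaged across
splits before comparison** — per-split true maps come from small matched
test groups (~20 subjects) and are individually too noisy — while the
accuracy gap is split-averaged. The cross-behavior correlation between
Δsimilarity and ΔCOD uses a twelve-behavior graded-similarity suite: a
correlation across behaviors needs a reasonably sized suite to carry
information, and the behavioral batteries this audit targets contain
several dozen measures.

## Study conditions and problem sizes

Desk-scale defaults throughout: 40 ROIs (780 edges), 500 subjects (400/100
majority/minority — the 80% imbalance of the motivating cohorts), weight
pattern correlation 0.3 for the biased condition and 1.0 (with equal
variances and no shift) for the null condition, population R² = 0.5. The
replicate studies use a single matched train/test split per replicate
(5 folds, fold 0 as test) with 500 null replicates for calibration and 50
for the recovery/validity rates; the orchestrated pipeline defaults to 3
matched splits with 30 draw iterations and 10 folds. The full-scale
settings of the audited procedure (10,000 draw iterations, 40 splits, 120
multi-site splits, 1000 permutations) remain the documented defaults of the
low-level operations and are plain config values.

## Numerical conventions and degenerate inputs

Population (1/N) denominators for SSE, SST, variances and covariances.
Correlations clipped to ±(1 − 1e−7) before Fisher z. Levene's test centers
on group means (original Levene); when both groups' absolute deviations are
constant but unequal, W diverges and is reported as (inf, 0) — a rejection.
Constant vectors make Pearson-based quantities undefined; they return NaN
with a warning rather than raising mid-pipeline. Greedy fold balancing
breaks ties deterministically by id/index. Kernel solves use a
positive-definite factorization with a symmetric-solver fallback for
indefinite kernels at tiny λ.

## Known limitations

* The latent FC covariance is a stand-in, not an estimate of any real
  cohort's RSFC structure; absolute accuracy levels here do not transfer.
* With 780 edges and ~400 training subjects, even noiseless behavior is
  not perfectly recoverable (minimum-norm fits reach COD ≈ 0.86, r ≈ 0.94);
  the noiseless "sanity ceiling" is therefore below 1 by design of the
  low-rank + diagonal covariance.
* The single-split replicate design trades the pipeline's repeated-split
  machinery for speed; it preserves the matched-comparison logic but not
  the split-to-split variance estimates.
* Matching cannot remove a distribution shift that the realized sample
  carries in a confound; validation flags it, and affected behaviors should
  be excluded rather than over-interpreted.
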