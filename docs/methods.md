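# Methods

## Problem setting

Intratumoral heterogeneity is invisible to whole-tumor ("Rad") radiomics:
averaging intensity and texture over the entire ROI discards the spatial
organization of the tumor microenvironment. Habitat radiomics instead
partitions each tumor into subregions with coherent imaging phenotypes and
extracts features per subregion. This package implements that pipeline for
two-phase contrast-enhanced CT (arterial ACE, venous VCE) with a binary
immunohistochemical label (Tim-3 expression high/low) as the prediction
target, together with the pathology arm (IHC H-scores, survival-optimal
dichotomization) and a synthetic-cohort generator that provides ground
truth for every stage.

## Preprocessing

CT intensities are clipped to a fixed −200..300 HU window and mapped
linearly to [0, 1]. The window is fixed rather than per-image min-max so
that a normalized intensity of, say, 0.5 means the same tissue density
(50 HU) in every patient. Volumes are resampled to 1 mm isotropic voxels
(trilinear for images, nearest-neighbor for masks) before any region
statistic is computed. Normalization is applied after resampling; the
order is exposed in the API for sensitivity analyses, but windowing and
trilinear interpolation nearly commute, so the choice is immaterial at the
tolerances used here.

## Habitat generation

Each ROI is oversegmented with SLIC on the joint two-channel (ACE, VCE)
normalized image, restricted to the ROI mask. Defaults: one superpixel per
~75 ROI voxels (minimum 60) and compactness 0.05 on the [0, 1] intensity
scale. Superpixels must be thinner than the subregions they are meant to
tile — in cm-scale tumors a habitat shell is only a few mm thick, so
coarse superpixels straddle boundaries and cap the achievable partition
accuracy regardless of how well the profiles cluster; the low compactness
lets boundaries track intensity edges. Superpixel profiles (mean ACE,
mean VCE) are standardized and clustered with K-means (K = 3, `n_init` =
10, fixed seed); every superpixel's voxels inherit its cluster. Connected
components smaller than `min_voxels` = 64 (a 4 mm cube at 1 mm spacing)
are merged into their largest adjacent region, so no habitat fragment is
too small for stable texture estimation.

Because K-means labels are arbitrary per patient, clusters are harmonized
("ReMap"): within each patient, raw clusters are ranked by mean normalized
ACE intensity and relabeled 1..K ascending, with ties broken by mean VCE
intensity and then voxel count. Harmonized label 1 is therefore always the
least arterially enhancing habitat (typically the core) and label K the
most enhancing (typically the rim). This rank-by-intensity rule is this
package's own definition of the harmonization step; alternative orderings
(e.g. by centroid radius) would serve the same purpose.

## Feature extraction

Features are computed in-house in three families per region and phase:

- **First-order** (18): moments, percentiles, energy, entropy/uniformity
  on discretized levels.
- **Shape** (12): voxel volume, mesh surface area (marching cubes),
  sphericity, maximum 3D diameter (convex-hull pairwise scan), PCA axis
  lengths, elongation, flatness, extent. Shape depends only on the mask,
  so it is identical between phases of the same region — used as an
  internal consistency check.
- **Texture**: GLCM (13), GLRLM (14), GLSZM (14), NGTDM (5), all on
  fixed-bin discretized intensities (bin width 0.05 on the normalized
  scale, i.e. 25 HU; at most 20 levels). Directional matrices use the 13
  unique 3D directions at distance 1; per-direction feature values are
  averaged, and directions with no valid voxel pairs are skipped rather
  than averaged in as zeros. Zones and neighborhoods use 26-connectivity.

Degenerate regions (single gray level) yield the standard limiting values
(contrast 0, correlation 1, entropy 0, …), never NaN, and the fallback is
logged. The per-region-per-phase feature count F is a property of the
configuration (F = 75 with the default families; studies using filtered
images report much larger F), so all table accounting is expressed in F:
the whole-ROI (Rad) table has 2F columns, the per-habitat table 2·K·F.
Early fusion is plain column concatenation with
`<phase>__<region>__<family>__<feature>` names. Both per-habitat and
habitat-averaged fusion modes are provided; per-habitat is the default
because it preserves the subregional signal the method exists to capture.

A sampled subset of the feature numerics (co-occurrence counts and
entropy, shape volume, first-order moments) is validated against
brute-force enumeration oracles in the test suite.

## Feature selection

Four nested stages, fitted on the training split only:

1. **ICC robustness** — ICC(2,1) (two-way random effects, absolute
   agreement, single measure) computed from the ANOVA decomposition; a
   feature survives if min(test-retest, inter-rater) ≥ 0.85. Undefined
   ICCs (zero variance) fail. Skipped for habitat signatures, whose
   regions are produced algorithmically rather than by a rater.
2. **Distribution screen** — Shapiro-Wilk per feature, survive at
   p ≥ 0.05. This reads the parametric-suitability intent of a
   distribution filter; a literal Student-t goodness-of-fit mode
   (KS against a fitted t) is available via `mode="t_fit"`, and the stage
   can be disabled.
3. **Pearson pruning** — repeatedly take the most correlated surviving
   pair with |r| > 0.9 and drop the member with the larger mean absolute
   correlation to the remaining survivors (lexicographic tie-break), until
   no pair exceeds the threshold.
4. **LASSO** — L1-penalized linear fit on standardized features along a
   60-point log-spaced λ grid with 10-fold CV; λ minimizing mean CV error
   is chosen (λ_min; a one-standard-error rule is available). Nonzero
   coefficients define the signature.

## Classification and evaluation

Five classifier families (logistic regression, random forest, extra
trees, XGBoost, LightGBM) run with library defaults, pinned seeds and
single-threaded fits for reproducibility; tree ensembles use 200–300
estimators and LightGBM's `min_child_samples` is lowered to 5 because the
cohorts here are small. The cohort is split 70/30 stratified. Evaluation
reports ROC/AUC with bootstrap CI, deciles-of-risk calibration,
Hosmer-Lemeshow (df = G − 2, degenerate bins merged), decision-curve net
benefit TP/n − (FP/n)·p_t/(1−p_t) on a 0.01–0.99 grid, and stratified
5-fold cross-validation. The headline AUC per signature is the best model
by test AUC, mirroring the study design this pipeline emulates; note this
best-of-five choice is itself optimistic on small test sets.

On the Hosmer-Lemeshow degrees of freedom: G − 2 is the classical
correction for probabilities fitted on the same data. For externally
supplied probabilities the statistic is approximately χ²(G); the type-I
calibration test therefore fits a logistic model per replicate, which is
the regime the G − 2 reference distribution is valid for.

## Pathology arm

H-score = 3·%high-positive + 2·%positive + 1·%low-positive, range 0–300;
replicate fields are averaged. Dichotomization puts the boundary in the
low group (low iff H-score ≤ cutoff, default 92.3). The Kaplan-Meier
estimator and two-group log-rank test are implemented directly from the
risk table (and cross-checked against lifelines in tests). The
survival-optimal cutoff re-implements the X-tile idea: scan all midpoints
between adjacent distinct scores, require each group to hold ≥ 10 % of
patients, and return the cutoff maximizing the log-rank chi-square. The
resulting p-value is reported unadjusted and explicitly flagged as
optimism-prone, since the scan is a multiple-look procedure.

Crude follow-up proportions (events/n × 100, one decimal) are provided for
end-of-follow-up rates; they equal Kaplan-Meier estimates only when no
censoring precedes the horizon.

## Synthetic cohort

The generator is first-class, tested code; it defines the conditions under
which the pipeline's claims are checked.

- **Geometry**: an ellipsoidal tumor (semi-axes drawn from 8–14 mm) placed
  randomly in a 48³ voxel, 1 mm volume; the normalized elliptical radius,
  perturbed by a smooth random field (amplitude 0.12), is split at its
  terciles into K = 3 contiguous shells (core → rim). Shells mimic
  rim/core enhancement patterns and respect SLIC's spatial coherence.
- **Intensities**: per habitat and phase, a mean HU level (ACE 40/110/180,
  VCE 60/100/145 — arterial contrast spread exceeds venous, so the phases
  are correlated but not redundant) plus Gaussian noise smoothed at a
  habitat-specific correlation length (1.0/1.75/2.5 voxels) and scaled to
  20 HU SD. Between-patient biology enters as a 20 HU SD jitter on each
  habitat mean and a lognormal (σ = 0.15) jitter on each texture scale.
  Background is 0 HU with 10 HU noise.
- **Tim-3 signal**: in the arterial phase of high-class patients, habitats
  2 and 3 exchange texture correlation lengths (habitat 2 gains +0.75
  voxels, habitat 3 loses the same; with the default scales this swaps the
  two), and habitat 2 additionally receives a +5 HU mean shift compensated
  volume-weighted in the other habitats. Both channels cancel at the
  whole-ROI level by construction: the shells have equal volume, so the
  ROI-level mixture of textures is class-invariant in distribution, and
  the volume-weighted ROI mean is unchanged; the residual histogram
  reshaping from the small mean shift sits below the per-habitat jitter
  noise. Per-habitat features, by contrast, see the full texture flip.
  This is the construction that makes the habitat-vs-whole-tumor
  comparison testable: the signal exists only as subregional organization,
  which whole-tumor aggregates marginalize away.
- **Labels and outcomes**: exactly round(n·0.5) patients are high, placed
  by a seeded permutation. IHC category percentages are Dirichlet draws
  with class-specific concentration — (6,4,2,1) for high (expected H-score
  215), (1,2,4,6) for low (≈ 85) — guaranteeing the simplex constraint.
  Overall survival is exponential with median 60 months in the low group
  and a hazard ratio of 2.2 for high; censoring hits a 0.3 fraction at a
  uniform fraction of the event time. Recurrence is Bernoulli (0.7 high /
  0.5 low).
- **Determinism**: every patient derives its RNG from
  `SeedSequence(seed, spawn_key=(patient_index,))`, so cohorts are
  bit-reproducible and individual patients can be regenerated in
  isolation.

Default cohort size is 102 patients in a 48³ volume — large enough for a
70/30 split and 10-fold selection CV while keeping a full 10-seed
benchmark within minutes on one core.

What the generator does **not** emulate: CT acquisition physics and
reconstruction kernels, organ anatomy and background tissue classes,
inter-phase registration error (phases are generated pre-aligned),
non-exponential hazards, and rater variability in ROI delineation.
Passing tests therefore demonstrate that the pipeline recovers planted
subregional structure and signal under controlled conditions — not that
it would achieve any particular performance on clinical CT.

## Numerical choices and edge cases

- Discretization clamps levels to [1, 20]; values outside [0, 1] (possible
  only for unnormalized input) are clipped into range.
- K-means ties and duplicate profiles resolve deterministically under the
  fixed seed; ReMap ties break by VCE mean, then voxel count.
- Small-region merging iterates until fixed point (bounded at 100 sweeps)
  because merges can create new undersized components; ROI voxel count is
  conserved exactly.
- An empty LASSO support (all coefficients shrunk away) backs off to the
  Pearson-stage survivors in the benchmark pipeline, with a warning, so
  the model comparison remains defined.
- Bootstrap CI resamples that lose a class are skipped.

## Known limitations

- The feature set is a compact IBSI-style core (F = 75); it does not
  include filtered-image (LoG/wavelet) channels, so studies quoting
  thousands of features per phase correspond to a larger F with identical
  accounting.
- The ICC arm requires externally supplied re-segmentation measurements;
  the synthetic generator does not currently simulate raters.
- Habitat count K is fixed by configuration (default 3); no data-driven
  selection of K is attempted.
- The best-of-five model choice and the cutoff scan are both reported
  without multiplicity adjustment, as in the emulated design; both are
  flagged where they appear.
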