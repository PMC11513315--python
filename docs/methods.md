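# Methods

## Intensity model and EM segmentation

Voxel intensities inside the lateral-ventricle mask are modeled as a
univariate K-component Gaussian mixture; K defaults to 3 for the three
tissues present there on T1 (CSF, choroid plexus, ventricular wall /
partial-volume voxels) and is exposed for sensitivity checks. The EM fit
uses:

* **Initialization**: deterministic quantile split of the sorted sample into
  K equal-count chunks (default), or seeded k-means. The quantile default
  makes `segment_cp` fully deterministic.
* **Convergence**: relative log-likelihood change < 1e-6, max 500
  iterations. The log-likelihood trace is stored and is non-decreasing (EM
  monotonicity; tested).
* **Variance floor**: 1e-6 × sample variance applied at every M-step,
  preventing component collapse onto repeated values. Variances are
  maximum-likelihood (1/n), including the K=1 closed form.

Tissue assignment happens *after* sorting components by mean, so it is
invariant to EM ordering: lowest mean → CSF, middle → CP, highest → wall.
This middle-cluster convention is the single most consequential choice in
the pipeline; it encodes the T1 contrast ordering (CSF darkest, CP
intermediate, partial-volume wall brightest) and fails by construction on
sequences with a different ordering.

Hard MAP labels are used rather than probability-weighted partial volumes
because the downstream volumetry consumes a binary mask.

**Degeneracy guard.** When the ventricle truly contains no intermediate
class (e.g. all-CSF intensities), EM still returns K components — it splits
one Gaussian into overlapping pieces — and naive MAP labeling would call
~1/3 of the mask CP. The fit is therefore flagged degenerate, and the CP
mask emptied, when the CP component's standardized separation from a
neighbor, |μ_CP − μ_nb| / √((σ²_CP + σ²_nb)/2), falls below 1.0
(configurable). On the phantom noise ladder used in testing the separation
never drops below ~2, so the guard cannot mask genuine segmentations there.

**Cleanup** replaces the expert's manual refinement with two rules, both
configurable: remove 26-connected CP components smaller than 5 voxels, and
remove CP voxels on the 1-voxel inner boundary shell of the ventricle
(wall contamination). The boundary shell uses the full 26-neighborhood, and
cleanup is idempotent.

**Bias field.** The stand-in estimator is homomorphic: log-intensities are
smoothed inside the mask with a broad Gaussian (mask-normalized convolution
so outside voxels do not leak in), mean-centered over the mask and
exponentiated. `scale_mm` trades off capturing the bias (smaller) against
absorbing anatomy (larger); the default 48 mm leaves an essentially flat
field (within ±0.3%) on unbiased phantoms of the default geometry, while
~24 mm visibly reduces within-class spread under a 0.2-amplitude simulated
bias. Bias correction is off by default in `segment_cp` because the phantoms
are generated bias-free unless asked otherwise.

## ALPS computation

The tensor volume stores six components (xx, xy, xz, yy, yz, zz) in mm²/s
with fixed anatomical axes (x left–right, y anterior–posterior, z
superior–inferior). Decisions where the procedure is conventionally
under-specified:

* **ROI**: sphere membership is by voxel-center distance in physical mm, so
  anisotropic grids behave correctly. The center is an explicit coordinate
  (in practice hand-placed); the hemisphere is metadata only.
* **Fiber classification**: dominant absolute component of the principal
  eigenvector; ties break z > y > x, so a perfectly isotropic tensor is
  labeled projection. Non-finite tensors are skipped and counted in QC.
* **"Maximum orientation"**: the representative voxel per class maximizes
  |dominant eigenvector component|, restricted to x-indices where both
  classes occur (the two fibers are read on one left–right line). Maximum
  fractional anisotropy is a conceivable alternative; alignment was chosen
  as the literal reading of orientation.
* **Diffusivities** are raw tensor diagonal entries at the selected voxels —
  "diffusivity along the x-axis" — not eigenvalues.

The index is scale-invariant and exactly 1 on isotropic fields (given
labels of both classes); both are tested, as is median recovery within 5%
under component noise of 5% of the smallest diagonal.

## Synthetic data

The T1 phantom is a pair of ellipsoidal ventricles (default semi-axes
7×13×9 mm at 1 mm isotropic resolution in a 64³ grid) with a three-class
partition: a 1-voxel inner wall shell, a contiguous posterior (low-y) CP cap
sized to a requested fraction of ventricle voxels, CSF elsewhere.
Contiguity matters because the cleanup rules would eat a salt-and-pepper CP.
Intensities are N(30, 4²)/N(60, 4²)/N(90, 4²) by default — inter-class gaps
of 7.5 SD, the "low-noise" regime in which segmentation is near-exact — and
the analysis scripts walk the SD ladder up to where Dice degrades. The TIV
(default 50,000 mm³) is a bookkeeping denominator chosen so that the
published CP percentages correspond to comfortable CP fractions of the
phantom ventricles; only the ratio is meaningful. A multiplicative bias
field (random quadratic in normalized coordinates, mean exactly 1, peak
deviation equal to the requested amplitude) can corrupt the image.

The tensor phantom places diagonal-tensor fiber boxes (projection: Dzz
maximal; association: Dyy maximal) over an isotropic background, with
additive component noise; voxels that lose positive-definiteness are redrawn
rather than clipped, preserving the symmetric noise law conditional on
validity. The default boxes abut at the grid center so the default 5 mm ROI
contains only fiber voxels of both classes on shared x-indices.

The cohort generator draws measured quantities directly from group models:
(CP%, word-list-recognition z) as a bivariate normal with the configured
correlation in the patient group, every other CERAD-K subtest
independently, ALPS from the group normal. Controls receive no cognitive
scores (the battery was administered to patients only), so correlation and
impairment analyses are patient-only. The shipped calibration uses the
published group values; the CP% SD, which the source does not print, is set
to 0.4 percentage points for both groups, back-computed from the published
within-patient comparison (difference 0.03 pp, p = 0.837 at n = 29/11
implies SD ≈ 0.4). Two CP% presets exist ("section3": 2.514/2.190, the
default; "abstract": 1.392/1.138) because the source prints both pairs; no
attempt is made to reconcile them.

What the simulations do *not* emulate: real ventricular anatomy and CP
shape, partial-volume mixing (the wall is a clean third class rather than a
CSF/parenchyma continuum), spatially correlated noise, registration error,
and DWI physics (tensors are generated, never fitted from diffusion-weighted
signals). Passing recovery tests therefore demonstrates correctness of the
computations and their calibration — not segmentation robustness on clinical
MRI.

## Recovery experiments and problem sizes

The calibration-recovery experiments (in `cpalps.calibration` and
`scripts/acceptance.py`) draw subject-level targets from a group model,
realize each as a phantom, and measure it end-to-end: 50 replicate cohorts
of the published group sizes (40/42) for the ALPS and CP% grand means, 200
cohorts of n = 40 for the correlation. ALPS phantoms are 16³ and noise-free
(the experiment tests the measurement chain, and the index is exactly
recoverable); T1 phantoms are 64³ at the default low-noise intensity model,
about 40 ms per subject to generate and segment. With ~2,000 subjects per
group the grand-mean standard error is ≈0.005–0.01 in the units of each
quantity, and recovered means are required to sit within 2 SEM of the
configured values (plus a 0.05 pp allowance for segmentation bias in the
CP% experiments, covering the one-voxel rounding and rare misclassified
voxels).

## Statistics

"Independent t-test" is implemented as Welch (unequal variances) by default
with the pooled Student variant available; the summary-statistic entry point
is the primitive and the sample version delegates to it, so both agree
exactly. Chi-square is Pearson's without continuity correction (Yates
optional). Pearson correlation p-values use the t transform with n−2 df.
Degenerate conventions: both-groups-zero-variance with equal means gives
t = 0, p = 1; |r| = 1 gives p = 0. No multiplicity correction is applied in
the primary report (each test at α = 0.05); Benjamini–Hochberg q-values are
available behind a flag as a clearly non-default extension. Test statistics
are verified against quadrature/brute-force oracles to 1e-8 in the suite.

The impairment rule is strict: a subtest counts only if z < −1.5 (exactly
−1.5 does not), a domain is affected if any of its subtests counts, and
impairment requires ≥ 2 affected domains. The domain→subtest mapping
(frontal/executive: verbal fluency, trail-making B, Stroop; language: Boston
Naming; verbal memory: word-list memory/recall/recognition; visual memory:
constructional recall; global: MMSE) is fixed in `cpalps.stats` since the
battery's domain names do not pin it down; "global" participates in
impairment counting like any other domain.

## Pipeline determinism

All randomness flows from numpy `default_rng` seeds. `run_all` derives each
subject's phantom seed as `SeedSequence((master, group_code, index))`, so a
subject's realization is independent of cohort size and reruns are
bit-identical; the output manifest records the config, its hash and the
seed.

## Known limitations

* The middle-cluster CP convention assumes T1-like contrast ordering.
* K = 3 assumes exactly the three modeled tissues; flow artifacts or septum
  would need either extra components or reliance on the cleanup rules.
* The ALPS ROI center must be supplied; no atlas-based placement.
* The cohort generator draws group models with normal tails; extreme draws
  (e.g. non-positive ALPS targets) are rejected by the phantom builders
  rather than truncated, which at the shipped calibrations is a >5σ event.
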