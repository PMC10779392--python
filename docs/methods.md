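# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `mbmri`. Nothing here states an empirical result
the test suite or `scripts/acceptance.py` does not itself compute.

## BOLD preprocessing

Inputs are assumed motion-corrected and pre-aligned to the atlas grid;
registration is out of scope. The voxel-mode pipeline order is fixed and
logged: brain mask → temporal band-pass → global-signal regression →
spatial smoothing. Region-series mode applies band-pass and regression
only.

**Band-pass.** Butterworth design with passband 0.008–0.2 Hz at TR 1.8 s
(Nyquist 0.278 Hz). The design order defaults to 2 and is applied
forward–backward (`scipy.signal.sosfiltfilt`), i.e. zero phase and an
effective order of 4. The series mean is removed before filtering so DC is
exactly zero. Padding uses scipy's odd-extension default with its
section-count-derived pad length; a fixed pad of 3 × order samples was
considered and rejected because at order 2 it leaves visible edge
transients. Filter order and passband are configurable.

**Global-signal regression.** The global signal is the unweighted mean over
in-mask voxels (voxel mode) or over regions (region mode). Each series is
replaced by its least-squares residual on {intercept, global signal}; the
residuals are exactly orthogonal to the regressor (checked to 1e−10). A
linear-detrend term can be added via a flag, default off: with the
band-pass already removing DC and slow drift, an extra polynomial term is
redundant in the default configuration.

**Smoothing.** Per-frame 3D Gaussian with σ_axis = FWHM / (2√(2 ln 2)) /
voxel_dim (FWHM default 0.3 mm at 0.275 mm voxels, σ ≈ 0.1274 mm). With a
mask, the kernel is renormalised inside the mask — smooth(data·mask) /
smooth(mask) — so no intensity bleeds in from the zeroed background and the
in-mask mean is preserved (to 0.1% in tests).

## Connectome construction

Region series are unweighted voxel means (no partial-volume weighting).
Connectivity is raw Pearson correlation; no Fisher z-transform is applied
before comparisons, because the downstream procedure compares correlation
patterns, not pooled correlation values. Edges are vectorised as the strict
upper triangle in row-major order over the fixed region ordering, each
classed intra-left / intra-right / inter-hemisphere. Multiple acquisition
runs are concatenated after per-run filtering and regression (averaging of
per-run connectomes is available behind a flag).

Degenerate inputs fail loudly: constant-in-time region series, fewer than 3
frames, and empty regions are errors naming the offender.

## Difference matrices and the discriminative network

Within-class pairs are unordered and counted once (C(5,2)=10 control,
C(7,2)=21 cKO at the default cohort); between-class pairs are oriented
control − cKO (35 pairs). All within/between-class statistics square the
per-pair correlations or use per-edge RMS aggregates, so they are invariant
to pair orientation.

Two aggregation routes are provided for class similarity, because the
construction of a single class-level R² is genuinely open:

* `pairwise_pattern_r2` — mean squared Pearson correlation over all cross
  pairs of difference vectors, with a seeded edge-label permutation null
  (default 10,000 draws);
* `class_pattern` + `class_pattern_correlation` — per-edge RMS of the
  difference values (the default summary), correlated across edges between
  classes.

Neither is claimed to reproduce any particular published class-level value;
the package's acceptance property is the qualitative dissociation: with a
subject-identity edge set shared by both groups and a disjoint group-effect
edge set, the control–control and cKO–cKO patterns correlate positively
while the discriminative network concentrates on the group edges.

The per-edge discrimination statistic is the squared point-biserial
correlation between edge strength and the binary group label across
subjects — the simplest statistic consistent with "edges that differentiate
the groups", isolated in one function (`edge_group_r2`) so alternatives can
be swapped. Binarisation retains edges with R² > 0.2 (configurable). Edges
with zero variance across subjects get R² = 0 with a logged warning rather
than an error. Under the null (any per-edge distribution exchangeable
across subjects, approximately Gaussian), R² follows Beta(1/2, (n−2)/2);
the calibration tests verify the empirical pass fraction and KS distance
against this closed form at n = 12 over 200 cohorts. Subjects flagged
`excluded` in metadata are dropped before pairing.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
verified.

**BOLD cohorts.** Defaults mirror the acquisition geometry: 5 control + 7
cKO subjects, 28 regions (14 per hemisphere), 1002 frames (3 runs × 334
repetitions) at TR 1.8 s. Subject i's target correlation is

    T_i = project_to_correlation(C0 + b_i ⊙ M_subj + 1[cKO] · Δ ⊙ M_grp)

with per-subject draws b_i ~ N(0, 0.15) on the subject edge set M_subj (20
edges), group offset Δ = +0.3 on the group edge set M_grp (10 edges,
disjoint from M_subj), and frames drawn i.i.d. Gaussian through the
Cholesky factor of T_i plus N(0, 0.2) observation noise per sample (which
attenuates observed correlations by 1/(1+0.04)). Effect sizes are chosen
for test power, not biological fidelity — no published effect sizes exist
for the real connectivity differences.

The base connectome C0 has macro-region block structure with elevated
homotopic correlations over a weak baseline, shrunk toward the identity
(factor 0.6 on off-diagonals, smallest eigenvalue 0.55). Default edge sets
are sampled with a node-degree cap (subject set ≤ 2 per node, group set a
matching). Both choices exist for the same reason: they keep C0 plus the
planted perturbations positive definite, so the eigenvalue-clipping repair
(floor 1e−6, diagonal renormalised) is a rarely-activated safety net rather
than a routine step, and the realised targets carry the planted effects
essentially exactly (sub-percent perturbation in the rare repaired case).
Without this, repair redistributes the planted offset onto off-target
edges and creates spurious systematic group differences.

What the generator does *not* emulate: hemodynamic response convolution,
temporal autocorrelation, physiological noise, motion. Passing tests
therefore demonstrate the correctness of the statistical machinery under
its stated model, not robustness to those real-data features.

**Brain phantoms.** Mirrored left/right blocks; per-subject region voxel
counts are base counts × group scaling (cKO only) × a multiplicative
jitter (σ = 0.02) shared between hemispheres so mirror symmetry is exact.
Default cKO scalings: 0.85 everywhere (global shrinkage), 1.2 on the
medulla, 1.0 on the ventricle labels — the qualitative pattern the
pipeline must detect. Truth is the rasterised voxel count × voxel volume,
recovered exactly by the volumetry stage.

**Angiograms.** Cylinders rasterised with flat end caps (voxel centre
within the axial extent and radial distance ≤ radius) at a vessel intensity
over Gaussian background noise. Tube phantoms used in tests centre the axis
at half-voxel offsets, the least-biased digitisation: at radius 4 voxels
the lumen count is within ~6% of πr²L and MIP footprints within ~3% of
their analytic areas.

**Morphometry.** Two independent normal samples; the percent-reduction
estimator carries a delta-method SE for the ratio of independent means.

## Volumetry and vascular measures

Region volume is voxel count × voxel volume, so per-subject region volumes
sum *exactly* to the labelled-voxel volume (conservation is asserted, not
approximated). Ventricle-flagged labels are excluded from brain-tissue
totals and reported separately. Normalisations: mm³/g (body weight) or
fraction of brain tissue volume. Per-region group comparisons default to
normalised volumes, uncorrected p-values (Benjamini–Hochberg behind a
flag); sex-stratified comparison is the same operation grouped by sex.

Thresholding is strict (`>`), so boundary voxels exactly at the threshold
are excluded — a documented deterministic convention. A per-axis MIP of a
segmented angiogram is dimensionally an area; the 3D lumen volume and the
nine (axis × threshold) MIP areas are computed and labelled distinctly, and
the vessel–brain relation is an OLS fit per combination with the mean ± SD
of R² across defined combinations.

## Statistics kit

`two_sample_ttest` wraps the standard pooled-variance test (df = n_a+n_b−2)
with a Welch option; an informational note is logged when the group
variance ratio exceeds 4, where the pooled assumption is doubtful.
Constancy is detected by exact range (ptp), not computed variance: the
variance of bitwise-identical values can evaluate to ~1e−31 dust, which
must not drive a t statistic. Two exact constants with equal values give
t = 0, p = 1; with different values the comparison is degenerate (an error
for the t-test; the percent-reduction estimator reports a certain
difference instead). The 2×2 chi-square uses no continuity correction
(df = 1) and warns when an expected count falls below 5. Type-I calibration
(rejection rate 0.05 ± 0.01 at α = 0.05 over 10,000 null simulations) is
part of the acceptance suite.

## Pipeline and problem sizes

`run_pipeline` executes the stages in fixed order, writes per-stage CSVs,
and emits a JSON report whose every headline number is traceable to a stage
output file; reports are cached by a hash of (config, cohort spec), and an
option withholds group labels until the analysis stages. The test suite and
acceptance script run the full-size cohort (12 subjects × 1002 frames × 28
regions) for the calibration and recovery checks, a 40-subject cohort for
planted-edge recovery, 200 cohorts for null calibration, and reduced frame
counts (240–600) for the pipeline integration tests — sizes chosen so the
whole suite completes in well under a minute of compute per module.

## Known limitations

* Region-level simulation is the default; the voxel-level painter exercises
  the preprocessing path but has uniform within-region signal.
* The class-level similarity statistics implement two defensible readings
  of an under-specified construction; absolute published values cannot be
  reproduced without the original raw data, and only sign structure is
  asserted.
* At n = 12 subjects the discriminative network necessarily contains
  ~14.5% of null edges (the Beta(1/2,5) tail above 0.2); interpretation at
  small n should lean on the calibration, not on edge counts.
* Angiogram phantoms are straight constant-radius tubes; no tortuosity,
  branching, or partial-volume intensity falloff.
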