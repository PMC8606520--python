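# Methods

## Background and scope

Diffusion-tensor "analysis along the perivascular space" (DTI-ALPS)
estimates how freely water moves along the perivascular spaces of the
deep medullary veins, a proxy for glymphatic function. At the level of
the lateral-ventricle body these veins run left–right (the image x
axis), perpendicular both to the corona-radiata projection fibers
(principal diffusion along z) and to the superior-longitudinal-fascicle
association fibers (principal diffusion along y). The index

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

therefore isolates the x-axis diffusivity component attributable to
perivascular fluid: the numerator averages the x diffusivity in both
fiber regions, the denominator averages the diffusivities perpendicular
to both the fibers and the x axis.

`dtialps` implements this analysis as a fully simulated, testable
pipeline for an ischemic-stroke cohort design: 50 patients with
unilateral cerebral infarcts and 44 controls, interhemispheric
comparison (ipsilateral vs contralateral to the infarct),
right-to-left/left-to-right ratio comparisons against controls,
infarct volume/ADC/FA measurement, and a regression battery relating
the ipsilateral index to clinical covariates. No real scans are
consumed: a phantom generator provides ground truth for every
downstream stage.

## Phantom model

The phantom is a 64×64×32 grid at 2 mm isotropic resolution (matching a
standard 2 mm DTI section thickness). Axis conventions: axis 0 = x
(right→left), axis 1 = y, axis 2 = z; the right hemisphere is x index
below the midline. Each hemisphere carries a 2×2-voxel projection-fiber
ROI and a 2×2-voxel association-fiber ROI (16 mm² in plane, matching
the reported mean manual ROI sizes of 18/16 mm²) on the single
ventricle-body slice, mirror-symmetric across the midline; a central
CSF ventricle block (isotropic 3.0×10⁻³ mm²/s) and isotropic background
tissue (0.75×10⁻³ mm²/s) complete the geometry.

Region tensors are diagonal in the image frame. The baseline supplies
the perpendicular diffusivities (Dyy_proj = Dzz_assoc = 0.7×10⁻³ mm²/s,
typical white matter; principal diffusivities 1.7×10⁻³). Given a target
index `a`, the solver sets Dxx_proj = Dxx_assoc =
a·mean(Dyy_proj, Dzz_assoc), so the phantom realizes `a` exactly — the
study only ever reports the index, never absolute diffusivities, so the
absolute baseline is a convention and only the ratio is validated.

Infarcts are grown voxel-by-voxel (nearest-first from a deep seed
point, deterministic tie-break) inside the affected hemisphere until
the target volume is met within one voxel, avoiding the ventricle and a
2-voxel guard band around the fiber ROIs — the clinical protocol
explicitly excludes infarcted tissue from the index ROIs, and the
guard band enforces that by construction. The infarct tensor is
prolate (principal axis z) with eigenvalues solved in closed form from
the target (ADC, FA) pair: with λ1 = m(1+2d), λ2,3 = m(1−d),
FA = 3d/√(3+6d²), hence d = FA/√(3−2·FA²). A hemorrhagic core, when
present, replaces the innermost 10% of lesion voxels (isotropic
ADC 400×10⁻⁶, FA 0.05) — hemorrhage counts toward lesion volume but is
excluded from the lesion ADC/FA means.

DWI synthesis uses the monoexponential tensor model
S = S0·exp(−b·gᵀDg) with one b=0 volume and 20 electrostatically
spread directions at b = 1000 s/mm² (the study protocol), and Rician
noise: the magnitude of the complex signal after adding independent
N(0, σ²) noise to both quadrature channels. Default σ = S0/50 (SNR 50),
chosen so tensor-fit bias in the ROI means stays well below 1% of the
index — the acquisition's true SNR is unreported.

## Tensor fitting and maps

The fit is plain (optionally weighted) log-linear least squares in the
six unique tensor elements plus ln S0, exact on noiseless data and
invariant to global signal scaling. Signals are floored at 10⁻⁶·S0
before the log; negative eigenvalues are clamped at 10⁻¹² mm²/s; both
event counts are reported for QC. FA, ADC (= trace/3), per-axis
apparent diffusivities (the tensor diagonal in the image frame) and a
directionally-encoded color map (channel = FA·|v1 component|) follow
the standard definitions. By default the pipeline fits only labeled
voxels (fiber ROIs, ventricle, lesion) — the only voxels any
measurement reads — which keeps a full 94-subject cohort at about
16 s on one core; `full_fit` fits every voxel for map export.

## Cohort calibration

The generator's defaults reproduce the published cohort tables; all
derived constants are computed in `default_cohort_config` from the
printed values, not fitted to pipeline output.

**Covariates.** Age, lesion ADC and FA are truncated normals at the
printed moments; sex, infarct side and hemorrhage are Bernoulli at the
printed prevalences (30/50 men, 32/50 right, 19/50 hemorrhagic).

**Time since onset** is a two-component stratum mixture on [1, 60]
days: an "early" scaled-Beta component on [1, 14] and a "late" one on
(14, 60]. The stratum fraction and both conditional means are solved in
closed form so that (i) the overall mean is the printed 17.1 days and
(ii) under the linear index–time model both time-stratified index means
(1.108 and 1.259) are exact in expectation. A single shifted log-normal
cannot satisfy these constraints together (its best fit puts only ~55%
of mass below 14 days and a late-stratum mean near 29 days), and
clinically a mix of acute-phase and follow-up imaging waves is a
reasonable description of a retrospective stroke cohort. Within-stratum
SDs (3.4 / 16.0 days) bring the overall SD to 14.2 vs the printed 14.8;
the solved stratum fraction is 0.657 vs the printed 32/50 = 0.64 — the
printed mean, stratum split and stratum index means are mutually
inconsistent by a small margin, and the calibration preserves the
graded quantities exactly.

**Infarct volume** uses the same stratified construction on
[4.12, 134.14] cm³: a small-lesion truncated-normal component below
20 cm³ (66% of patients, the printed split) and a large-lesion one
above, with component means chosen to keep the overall mean at
34.07 cm³. Volume and time are coupled through a Gaussian rank copula
with ρ = −0.6956, solved once so that the expected time among
small-lesion patients reproduces the volume-stratified index mean
(1.189). The implied time–volume correlation (≈ −0.43) also reproduces
the univariable volume coefficient (β ≈ −0.35 vs the printed −0.348)
without any separate adjustment.

**ALPS targets.** The contralateral index is N(1.335, σ_C); the
ipsilateral index is ratio-mediated: ipsi = q·contra with
q = α_side + (B/1.335)·t + ε, where B = 0.007/day is the printed
index-on-time slope and the side-specific levels α give
E[q | right] = 0.84 and E[q | left] = 0.92, the printed ratio means. So
E[ipsi | t] is exactly the linear model intercept + B·t, and the
subject-level ipsi/contra ratio has exactly the printed side-specific
means — which an additive model with an independently distributed
contralateral index cannot achieve (mean-of-ratios ≈ 0.88 there). The
residual SD σ_C is solved from the standardized-coefficient identity
β = B·SD_time/SD_ipsi = 0.794, giving σ_C ≈ 0.056 and an implied
ipsilateral SD of 0.125 (printed: 0.126). The price is the
contralateral within-cohort SD (0.056 vs the printed 0.160): the
published per-hemisphere SDs, side-specific ratio means and
standardized time coefficient are jointly infeasible for any
two-moment model, and this
calibration sacrifices the one ungraded quantity. Controls draw a
left-hemisphere level N(1.37, 0.14) (control absolute levels are
unreported) and a right-to-left ratio N(0.95, 0.07), the printed
control ratio distribution.

**Observers.** Optionally two simulated raters re-measure each
hemisphere with N(0, 0.057²) jitter; 0.057 is solved from the bilateral
index variance so the expected two-way random absolute-agreement ICC is
0.838, the reported inter-observer agreement. The default is a single
measurement: the published regressions used observer-averaged values,
which the truth targets already represent, so enabling jitter for the
calibration cohorts would double-count measurement noise.

## Statistics

Paired t (scipy), ANCOVA as the linear model outcome ~ group + age +
sex with marginal means at the pooled covariate averages (statsmodels),
one-sample KS normality against the moment-matched normal, VIF,
univariable OLS with standardized coefficients (β = B·SDx/SDy, equal to
Pearson r in the simple case), and forward/backward stepwise selection
(enter p < 0.05, remove p > 0.10, the defaults of the commercial
package used in the study; configurable). ICC(A,1) is computed from the
two-way ANOVA mean squares with the F-based confidence interval
(Satterthwaite degrees of freedom); pingouin is used as an independent
oracle in the tests, never as the implementation. Ratio ANCOVAs are
reported on the native ratio scale. All tests are two-sided at
α = 0.05. Sex is coded woman = 0, man = 1.

The report generator emits four tables mirroring the study's results
layout: cohort descriptives; ratio ANCOVAs (right-to-left for
right-infarct patients vs controls, left-to-right for left-infarct
patients vs controls); index means stratified at 20 cm³ and 14 days
with covariate-adjusted differences; and the univariable plus stepwise
multivariable regression of the ipsilateral index on age, sex, volume,
ADC, FA, hemorrhage and time. Empty strata and degenerate designs are
flagged in the report notes rather than failing the run.

## Reproducibility and problem sizes

Every random draw descends from a single master seed (cohort sampling,
per-subject DWI noise seeds, observer jitter), so cohorts and reports
are bit-reproducible and per-subject processing is order-independent.
The acceptance computation uses 20 end-to-end replicate cohorts
(94 subjects each, full imaging) for the group statistics and 50
table-level replicate cohorts for the regression coefficients; grand
means are compared with the published values within twice the
Monte-Carlo standard error across replicates.

## Limitations

The phantom has no anatomy beyond the structures the index reads — no
partial-volume effects, gyral folding, distortion or motion, and ROI
placement is exact rather than operator-dependent, so passing tests
validate the measurement chain and statistics, not robustness to
registration or segmentation error on real scans. Region tensors are
piecewise constant; real periventricular diffusivity varies smoothly.
The stratified time/volume mixtures encode the printed strata rather
than a mechanistic imaging-delay model. Absolute diffusivity baselines
are conventions (only the index is constrained by the study), and the
contralateral index dispersion is deliberately narrower than printed,
as discussed above.
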