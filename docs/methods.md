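# Methods

`dtialps` implements the DTI-ALPS ("analysis along the perivascular
space") index together with everything needed to validate it end to end
on synthetic data: a multi-tensor diffusion-MRI phantom with known
ground truth, a diffusion tensor fit, constrained spherical
deconvolution with fixel segmentation for the crossing-fibre
"complexity" covariate, derived clinical scores, and the
group-comparison / regression statistics used in cohort studies of
Lewy body dementia.

## The ALPS model

At the level of the body of the lateral ventricle, medullary veins run
left–right (x), perpendicular to the superior longitudinal fasciculus
(SLF, association fibres, anterior–posterior / y) and the superior
corona radiata (SCR, projection fibres, superior–inferior / z).  Water
movement along the perivascular sheaths of those veins adds x-axis
diffusivity inside both tracts.  The index is

    ALPS = mean(Dxx_SCR, Dxx_SLF) / mean(Dyy_SCR, Dzz_SLF)

where each `D**` is the arithmetic mean of the corresponding
scanner-frame tensor diagonal (not an eigenvalue) over one ROI.  The
outer "mean" is the unweighted two-term average of ROI means, i.e. the
literal two-argument mean in the defining formula, not a voxel-pooled
mean — with equal-sized ROIs the two coincide, but we keep the literal
reading.  ALPS is computed per hemisphere and the bilateral value is
the arithmetic mean of the two.  An isotropic medium gives exactly 1;
perivascular x-axis water pushes the ratio above the tract-only
baseline.  The index is invariant to uniform scaling of all
diffusivities.

## Phantom

`build_alps_phantom` places four spherical ROIs (default radius 2
voxels) on a 32×12×12 grid of 2 mm voxels, well separated along x and
mirror-symmetric about the midline.  SLF ROIs contain y-oriented fibre
populations, SCR ROIs z-oriented ones (axial/radial diffusivity
1.7/0.3 ×10⁻³ mm²/s, typical deep white matter), mixed with a
perivascular compartment of fraction 0.1 whose tensor has dominant
x-axis (2.0/0.4 ×10⁻³ mm²/s).  Background voxels are isotropic
(0.8 ×10⁻³ mm²/s).  A configurable fraction of ROI voxels receives a
second, orthogonal fibre population of equal weight ("crossing
fraction"), which is what the complexity metric is designed to detect.

The acquisition scheme reproduces the study protocol: shells at
b = 50 (17 directions), 300 (8), 1000 (64) and 2000 (64) s/mm² plus a
b=0 volume.  Direction sets use a deterministic spherical-Fibonacci
lattice rather than vendor tables, so a given shell specification
always produces the same scheme.

Two compartment-mixing regimes are available.  The default, `tensor`,
generates each voxel's signal from the fraction-weighted mean tensor
(fast exchange); under it the noiseless tensor fit is exact and the
fitted pipeline reproduces the analytic ground-truth ALPS to machine
precision, which is the regime used to validate the index arithmetic.
`signal` mixing sums per-compartment signals (slow exchange, the
standard multi-tensor forward model); it is non-mono-exponential, so a
tensor fit carries a bias that grows roughly linearly with b
(measured: ~6×10⁻⁶ mm²/s at b=50, ~1×10⁻⁴ at b=1000 for an equal 90°
crossing), and it is the regime used for the FOD/complexity
experiments.  `simulate_voxel_signal` itself always mixes at the
signal level.

Noise is Rician by default — the magnitude of a complex Gaussian
perturbation — at SNR 30 on the b=0 signal, typical of 3 T diffusion
MRI.  The noise seed is separate from the geometry seed, so two
phantoms differing only in noise share identical ground truth.

What the phantom does *not* emulate: partial-volume CSF/GM, spatially
varying S0, susceptibility or eddy artefacts, motion, template
registration, and anatomy outside the four ROIs.  Tests passing on the
phantom therefore validate the estimators and their arithmetic, not
robustness to the full preprocessing chain real data require.

## Tensor fit

Log-linear least squares on volumes with b ≤ `max_b` (default
1000 s/mm², keeping the three lower shells where the Gaussian model is
reasonable), followed by one weighted re-fit with weights equal to the
squared predicted signal.  Signals are floored at 10⁻⁶·max before the
log.  Non-positive-definite voxels are flagged but not altered, since
ALPS consumes raw diagonals.  No outlier rejection or free-water
elimination.

## FOD, fixels, complexity

Single-shell (default b=2000), single-tissue constrained spherical
deconvolution in a real even spherical-harmonic basis (default
L_max = 8, 45 coefficients against 64 directions).  The single-fibre
response is estimated by rotating candidate voxels' gradient frames so
the fibre lies along +z and projecting jointly onto zonal harmonics;
at L_max = 8 the zonal truncation of the b=2000 profile leaves a
residual of about 5×10⁻⁴, which is immaterial for peak geometry.
Non-negativity is enforced iteratively on a 300-point sphere grid
(threshold 0.1 × the mean positive amplitude of the initial estimate),
stopping when the constraint set stabilises or after 50 iterations.

Fixels are obtained by a discrete watershed on an antipodally
symmetric 600-point grid: every grid point is assigned to its
steepest-ascent local maximum, antipodal maxima are merged, peak
orientations are refined by continuous maximisation of the SH
amplitude, and peaks below 0.1 × the largest peak are discarded.  A
fixel's fibre density is the amplitude-weighted mass of its watershed
lobe.  This replaces Bingham lobe fitting with a simpler construction
that yields the same lobe-integral quantity, which is all the
complexity ratio uses.  With densities f₁ ≥ … ≥ f_N,

    complexity = 0                       if N ≤ 1
               = (N/(N−1)) (1 − f₁/Σf)   otherwise,

which is 0 for a single bundle, 1 for N ≥ 2 equal bundles, lies in
[0,1], and is invariant to uniform rescaling of the densities.  On
noiseless phantoms two-fibre crossings are resolved down to 45° at
L_max = 8; narrower crossings merge into one fixel, a known resolution
limit of order-8 deconvolution.  The subject-level covariate is the
mean of the four ROI-mean complexities (the voxel-pooled alternative
is available by averaging the map directly).

## Cohort generator

`simulate_cohort` draws per-group ALPS, age, sex and clinical columns.
Defaults mirror the study population: n = 26 controls / 60 PD-NC / 35
PDD / 51 DLB with the published age and sex structure, ALPS residual
SD 0.15, and group means chosen so the standardized separations equal
the reported effect sizes of the two vs-PD-NC contrasts (1.29 for DLB,
0.57 for PDD; the implied DLB-vs-PDD separation is then 0.72, close to
but not exactly the reported 0.68, because the three reported d values
are not mutually consistent with any single set of three means).
Clinical outcomes are linear in ALPS, age and sex with Gaussian
residuals; default slopes take the magnitudes of the unadjusted
regression coefficients (e.g. MoCA slope 9.6 per ALPS unit).  Outcome
values are deliberately not clipped to instrument ranges, so the
linear-recovery tests remain exact; real instruments truncate.

## Statistics

All linear models run through one least-squares engine with explicit
design matrices (treatment coding, first sorted level as reference).
The omnibus group test is a full-vs-reduced F: the reduced model drops
the group factor and keeps the covariates.  Planned contrasts are
two-group ANCOVAs with the same covariates; Cohen's d is the
covariate-adjusted mean difference divided by the pooled residual SD
of that two-group model (with no covariates this reduces to classical
pooled-SD d).  Benjamini–Hochberg adjustment is applied within named
families (the six pairwise contrasts; each regression outcome family
per covariate set).  VIF_j = 1/(1−R²_j) from regressing predictor j on
the remaining predictors plus intercept.  The hemisphere comparison is
a paired t-test.  Kruskal–Wallis (tie-corrected) or the two-sample
rank-sum W covers the demographic-table comparisons, with a
tie-corrected Dunn z post-hoc.  Missing data are handled by listwise
deletion per analysis, with the analysed n reported.

Monte-Carlo calibration (`dtialps.simulate`) checks the machinery
against known truth: under the null the omnibus ANCOVA rejects at the
nominal 5% (2000 replicates, within the binomial band), and injected
covariate-adjusted standardized differences at the study's group sizes
are recovered with mean bias below 0.02 over 1000 replicates (the
small upward residual is the usual 1/(4·df) small-sample inflation of
d plus magnitude folding, both well inside the ±0.05 check).

## Clinical scores

The composite cognitive score is the mean of z-scored components —
MoCA plus one prioritised task per domain (Stroop colour naming,
category fluency, letter fluency, Hooper) — with timed tasks
sign-flipped so higher is better; the reference population for
z-scoring defaults to the control group, the conventional choice.  The
NPI-4 estimate is a runtime-configured mapping (ordered source lists
with weights, first available source wins, provenance recorded), since
the item-level mapping is site-specific.  The LBD symptom composite
averages z-scored NPI-4 estimate, UPDRS-III, DCFS and MoCA
(sign-flipped), severity-aligned; a raw-average option exists.
Vascular risk is the count of seven history items (0–7).  SVD burden
awards one point each for ≥1 lacune, ≥1 microbleed, basal-ganglia
EPVS grade 2–4, and Fazekas 2–3 (0–4).  Inclusion filters drop
controls with MMSE < 25 and patients more than 10 years (inclusive
bound, configurable) from the relevant diagnosis — the dementia
diagnosis for PDD and DLB, parkinsonism onset otherwise.

## Numerical choices and degenerate inputs

Exact-fit ANCOVAs (RSS at rounding level in both models) return F = 0
rather than a 0/0 ratio.  A paired t-test on constant nonzero
differences raises instead of returning an infinite t.  Flat FODs
produce no fixels (local maxima must be strict).  Empty ROIs,
all-NaN ROIs, rank-deficient designs (with the aliased columns named),
overlapping left/right ROIs, out-of-range clinical ratings and
negative fibre densities all raise informative errors.  Problem sizes
were chosen so the full validation suite runs in a few minutes on one
CPU: the default phantom grid is 32×12×12 with CSD restricted to ROI
voxels, and the Monte-Carlo runs use 1000–2000 replicates.
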