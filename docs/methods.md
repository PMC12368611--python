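# Methods

This note documents the models, parameter choices, and numerical decisions
behind `cortexdti`, and what the synthetic data can and cannot establish.

## Coordinate and data conventions

World coordinates are RAS millimetres. Voxel indices are 0-based and the
affine maps voxel *centres* to world coordinates. Diffusivities are in
mm²/s, b-values in s/mm². The three cortical surfaces (inner = WM/cortex,
mid-thickness, outer = cortex/CSF) share one triangulation and are
index-paired: vertex *i* corresponds across all three meshes, which is what
makes per-vertex thickness well defined.

## Diffusion signal model and tensor fit

Synthesis and fitting both use the mono-exponential tensor model
S = S₀·exp(−b·gᵀDg). The default acquisition emulated by the phantom is
6 b=0 volumes plus 30 directions at b = 1000 s/mm², the directions drawn
from an electrostatic-repulsion set shipped as an editable fixture
(`data/gradients30.txt`; any well-spread 30-direction set works — minimum
pairwise separation of the shipped set is 25.6°).

The fit is log-linear least squares on ln S with the b=0 volumes averaged
into a single sample first (this improves design conditioning and is
standard practice at b = 1000). A linear fit was chosen over nonlinear
because it is exactly invertible — the noiseless phantom round-trip is an
identity to ~1e-15 — which turns tensor-fit testing into a
machine-precision check. An optional single-iteration WLLS reweighting
(weights ∝ squared predicted signal) is available. Non-positive signals are
dropped per voxel; a voxel is removed from the mask if fewer than 7 usable
samples remain. Negative eigenvalues are clamped to zero (with a reported
count) rather than rejecting the voxel: the cortical ribbon is thin, and
the downstream MD/FA vertex filter already removes pathological vertices.

Noise is Rician: two independent Gaussian channels of standard deviation
s₀/SNR, magnitude taken. This reproduces the positive bias of magnitude MRI
at low SNR (the phantom tests assert the bias direction at SNR ≤ 5).
Non-central-chi noise from multi-channel reconstruction is deliberately not
simulated; preprocessing pipelines convert the signal distribution toward
Gaussian/Rician before fitting, so Rician is the relevant regime.

## Phantoms

Two analytic geometries, deliberately minimal:

* **Slab** — flat cortex between z = 0 and z = thickness; all three
  surfaces share (x, y) per vertex, so paired-vertex thickness equals the
  planted separation *exactly* and the surface normal is exactly +z. The
  tensor's principal eigenvector makes a configurable angle with +z, so
  ground-truth radiality is |cos(tilt)| at every vertex.
* **Shell** — concentric icospheres (topology shared, vertices scaled to
  radii r, r+t/2, r+t) with a radial tensor field. This exercises normal
  estimation and nearest-neighbour sampling error under curvature. Lobe
  labels are five equal 36°-latitude bands (frontal, parietal, insula,
  temporal, occipital from the +z pole) and hemispheres split at x = 0 —
  fixed, deterministic rules applied identically to vertices and voxel
  centres, so planted per-lobe values are recoverable by regional
  averaging.

No folded-gyrus phantom is provided: gyral/sulcal stratification is outside
the scope of the analysis these phantoms validate. Default eigenvalues are
(1.0, 0.75, 0.75)×10⁻³ mm²/s (MD 0.83×10⁻³, FA ≈ 0.17 — cortex-like, and
safely inside the vertex-filter thresholds); default voxel size 1.5 mm
isotropic.

## Surface metrics

Vertex normals are the normalized **area-weighted** sum of incident face
normals (raw cross-product accumulation). On the subdivision-3 icosphere
they deviate from the true radial direction by at most ~0.7°, halving per
subdivision level; this is the dominant systematic error in shell-phantom
radiality (mean radiality ≥ 0.998 there).

Sampling is nearest-neighbour — also for the eigenvector field, where
interpolation would face a sign ambiguity (ê₁ and −ê₁ are equivalent).
World→voxel rounding is **half away from zero**, fixed and documented so an
exhaustive nearest-voxel oracle reproduces the lookup bit-for-bit (up to
genuine distance ties, which either convention may break). Vertices mapping
outside the grid or onto unmasked voxels are excluded.

The vertex filter excludes vertices with MD > 1.5×10⁻³ mm²/s or FA > 0.3;
the inequalities are strict, so boundary values are kept. The filter
applies to all five DTI-derived metrics. Thickness is computed over all
paired vertices regardless of the DTI filter by default — the filter
targets DTI sampling artifacts, not geometry — with
`thickness_uses_filter=True` available to force a common vertex set.

Regional summaries cover the total cortex (all lobe-labelled vertices
pooled) and the five lobes, for left, right, and "both" hemispheres, where
the "both" value is the mean of the left and right regional means (matching
the convention of averaging hemispheres before group analysis). The total
row equals the included-vertex-weighted combination of the lobe rows by
construction.

## Cohort simulator

The simulator emulates a cross-sectional lifespan cohort of regional metric
means: n subjects (default 190), ages 5–74 (uniform by default, or drawn
from an editable 5-year-bin histogram fixture that represents a plausible
recruitment shape — it is explicitly not digitized from any published
figure), sex Bernoulli(0.5) with **no effect** (the sex null is true), and
per-spec values mean(age) + u + e_h, where the shared subject effect u and
hemisphere term e_h split the residual variance to give Var = noise_sd² and
Corr(left, right) = ρ (default 0.8). Residuals are Gaussian (matching the
OLS fitting assumption); a Student-t(4) option exists for robustness
experiments.

Default noise SDs — 0.1 mm (thickness), 0.02 (radiality), 0.01 (FA),
0.02×10⁻³ mm²/s (MD/AD/RD) — are set at roughly 1–2× the
practical-significance margins, so recovery tests are informative rather
than trivial.

The reference whole-cortex generating curves are solved at run time from
landmark anchors of the reported healthy-lifespan course: thickness
exponential through (5 y, 2.87 mm) and (30 y, 2.60 mm); radiality cubic
through (5, 0.76), (19, 0.73), (55, 0.71), (74, 0.65); FA Poisson-type with
minimum (30 y, 0.12) and through (5, 0.14); MD/AD/RD quadratics with
vertices at 34/36/32 y and endpoint values (0.83, 0.84)/(0.94, 0.95)/
(0.77, 0.78)×10⁻³ mm²/s. Two derived values are design choices rather than
anchors: the thickness value at 74 (2.55 mm, encoding "minor gradual
decrease after 30") and whatever each interpolant implies between anchors
(the radiality cubic stays within 0.711–0.729 over ages 20–54, i.e. the
intended plateau).

**What passing recovery tests shows — and doesn't.** The simulator
reproduces the *statistical* structure the analysis assumes (trajectory
shape, residual scale, hemisphere correlation, null effects). It does not
model age-dependent heteroscedasticity, non-uniform dropout, site or
scanner effects, spatially correlated vertex noise, or segmentation
failures, so passing tests certify the estimation machinery, not the
robustness of the conclusions to those real-world complications.

## Trajectory fitting and model selection

The five families and parameter counts k: linear (2), quadratic (3), cubic
(4), Poisson-type a + b·t·e^(−ct) (3), decreasing exponential a + b·e^(−ct)
(3). The Poisson-type curve is the 3-parameter non-symmetric lifespan shape
used in white-matter DTI modelling; with b < 0 its single minimum sits at
t = 1/c. The exponential family is constrained to b ≥ 0 at refinement
(decreasing trajectories); if the unconstrained linear part turns negative
the family degenerates to a flagged constant fit.

Polynomials are solved in closed form. The nonlinear families use variable
projection: c is profiled over 200 log-spaced grid points spanning
time constants of 0.5–200 years (c ∈ [1/200, 2] yr⁻¹), with the linear
part solved in closed form at each c, followed by bounded scalar refinement
between the neighbouring grid points (xatol 1e-10). The procedure is fully
deterministic, and noise-free generating parameters are recovered to
≤1e-8 relative error.

AIC = n·ln(RSS/n) + 2(k+1): Gaussian likelihood with the error variance
counted as a parameter and constants dropped (only differences within one
dataset matter). AICc is not used — n = 190 ≫ k. An RSS at rounding level
(≤1e-20·n·max|y|²) is treated as an exact fit with AIC = −∞, so selection
among exact fits reduces to fewest parameters. Selection: candidates are
all fits within two AIC units of the minimum; the fewest-parameter
candidate wins; ties on k go to the lower AIC, and exact ties to a fixed
precedence order (linear, quadratic, cubic, poisson, exponential).

Landmarks are closed-form where possible (quadratic vertex −b/2c, Poisson
extremum 1/c, cubic stationary points from the derivative's real roots),
reported only within ages 5–74, with endpoint values at 5 and 74 always
included; monotone families report endpoints only.

A consequence of the parsimony rule worth knowing: when the planted
curvature is small relative to noise — the MD and RD quadratics rise by
only 0.01×10⁻³ mm²/s over 40 years against a residual SD of 0.02×10⁻³ —
linear or Poisson fits are legitimately selected in a substantial minority
of replicates. Median landmark estimates across replicates remain accurate
(within ~1 year for the diffusivity minima), but per-replicate
family-recovery rates above 80% hold only for the better-identified curves
(the radiality cubic, the FA Poisson, and the AD quadratic among the
planted set). This is a property of the selection rule at that
signal-to-noise, not an estimator defect.

## Group statistics

Hemisphere comparisons: Wilcoxon signed-rank on left−right differences,
zeros dropped; the exact null (tie-aware, via the rank generating function)
for up to 25 nonzero pairs, the normal approximation with continuity and
tie correction above that; fewer than 6 nonzero pairs → flagged
underpowered, no p-value. Sex: Mann–Whitney U on hemisphere-averaged
subject means (exact for small tie-free samples via scipy). Lobes: one-way
ANOVA, then Tukey HSD for all 10 pairs; Benjamini–Hochberg FDR is applied
across the 10 pairs within one metric (the FDR family is not uniquely
defined by the analysis description; this choice is configurable by
post-processing raw p-values), and the Tukey familywise p is reported
alongside for reference while the BH-adjusted p drives the significance
flag.

Significance is a pure conjunction: BH-adjusted p < 0.05 **and**
|median(A) − median(B)| above the metric's practical margin. The group-wise
median difference is the default reading; a paired alternative (median of
per-subject |differences|) is available for subject-aligned groups. Under
the simulated null the paired test's type-I error is calibrated to nominal
α = 0.05 (checked against the binomial band over 1000 seeds).

## Pipeline and reproducibility

`RunConfig` (pydantic, `extra="forbid"` so unknown keys fail by name)
surfaces every analysis constant — exclusion thresholds, margins, cohort
size, seeds — as a named field whose defaults are the canonical values
above. Each run writes the resolved config and a provenance record
(versions, seeds, masked/excluded counts) beside its outputs, and repeated
runs with the same config are byte-identical.

Problem sizes in the test suite and acceptance script — slab extents of
15–30 mm at 1.5 mm voxels, 200 cohort replicates of 190 subjects — were
chosen so the full validation chain runs in well under a minute on a single
CPU while keeping Monte-Carlo medians stable to well inside the asserted
tolerances.

## Known limitations

* No folded geometry: curvature effects on radiality are exercised only by
  the smooth shell; high-curvature sampling variability is untested.
* Single-shell, Gaussian-tensor signal only; no multi-compartment models.
* The phantom simulates Rician, not non-central-chi, noise.
* The cohort simulator's residual model is homoscedastic in age.
* Bootstrap confidence intervals for trajectory landmarks are not
  implemented; only point estimates and across-replicate spreads are
  reported.
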