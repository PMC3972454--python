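# Methods

## The additive model

The modelling core fits Gaussian additive models of the form

    y_i = β₀ + f(x_i) + Σ_j g_j(z_ij) + ε_i,   ε_i ~ N(0, σ²)

where `y` is a continuous measure (e.g. total cortical surface area in
mm²), `x` is the independent variable of interest (typically age at
imaging exam, in years), and the `z_j` are covariates entering linearly,
as factors, or — for the interaction variable — as a factor main effect
plus per-level deviation terms.

**Smooth terms.** Each smooth is a cubic B-spline expansion with 10
basis functions on equally spaced knots over the observed predictor
range, penalized by the squared second-order differences of its
coefficients (a P-spline). The penalized least-squares problem

    min_β ||y − Xβ||² + λ βᵀSβ

is solved over a log-spaced grid of 34 penalty weights λ ∈ [10⁻³, 10⁸];
λ is selected by minimising the generalized cross-validation score
n·RSS/(n − tr(H))². One λ multiplies the whole smooth penalty — a
deliberate simplification that keeps the per-vertex mass-univariate
loop cheap and is adequate when a model has one dominant smooth (the
independent variable) plus deviation smooths that share its scale.
With no smooth terms S = 0 and the fit is exactly ordinary least
squares; this linear special case is pinned by tests against a
normal-equations oracle at 1e-8.

**Identifiability.** Every smooth is constrained to sum to zero over
its observed rows; the constraint is absorbed by reparameterising the
basis into the null space of the constraint vector, so the design stays
full rank next to the intercept and the rank check stays meaningful.
Interaction smooths are *deviation* smooths: the reference level of the
interaction factor follows the main smooth, each other level adds a
penalized deviation curve centred within that level. This makes the
three inferential blocks — independent variable, interaction main
effect, interaction — distinct and separately testable, and implies
that the factor main-effect coefficient estimates the mean response
difference between levels averaged over the non-reference level's
predictor distribution (the quantity the synthetic truth sidecar
records as the recovery target).

**Covariate logic.** System covariates default on: scanner device as a
factor; socio-economic measures; genetic ancestry factors. Ancestry
factors are proportions summing to one, so of K columns only K−1 enter
(the last in lexicographic order is dropped); the untruncated design is
detected as rank deficient by a QR-with-pivoting check on unit-scaled
columns, which names the collinear columns. Non-numeric covariates are
promoted to factors at fit time. SES measures enter as linear terms on
their ordinal codes: levels are treated as equally spaced, which keeps
"the SES slope" a single estimable quantity; users wanting
level-specific effects can pass the column as a factor covariate.
Sessions missing any model variable are removed first (listwise
deletion); repeated visits of one subject trigger a warning that the
analysis stream is cross-sectional and does not model within-subject
correlation.

**Inference.** The coefficient covariance is the frequentist sandwich
σ̂²·A⁻¹XᵀX·A⁻¹ with A = XᵀX + λS and σ̂² = RSS/(n − edf), edf = tr(H).
Unpenalized blocks get exact Wald/F tests. Penalized blocks use a
rank-truncated Wald statistic (eigen-truncation of the block covariance
at the rounded block edf) against an F reference — an approximate test:
its null distribution is mildly anti-conservative, which is acceptable
for exploratory ranking of terms and is why multiplicity control
downstream (FDR) is computed from the same p-values that users see.
Variance explained is 1 − RSS/TSS; for the Gaussian identity-link model
this coincides with deviance explained, and both names are exposed.
Adjusted R² uses the penalized fit's effective degrees of freedom. AIC
and BIC use the Gaussian log-likelihood with edf + 1 parameters (the +1
is the scale), and model comparison refuses fits on different session
subsets, where information criteria are not comparable.

## Vertex-wise surface statistics

The same model is refit at every mesh vertex with the vertex measure as
response. Only the response changes, so the design matrix and the
per-λ factorizations are computed once and shared; per vertex the loop
reduces to a p-vector solve per λ plus GCV selection, which keeps a
642-vertex hemisphere at n=800 sessions well under a second. Vertices
with a constant measure are degenerate and get p = 1, zero effect. The
per-vertex effect size is the least-squares slope of the predicted
curve over the predictor grid — a signed summary that equals the
regression slope for linear fits.

Multiple comparisons are controlled by the Benjamini–Hochberg step-up
rule: the significance threshold is the largest sorted p-value p(i) ≤
(i/m)q, with a 0 sentinel when nothing passes; q defaults to 0.05. FDR
is computed per map over all supplied vertices (both hemispheres pooled
when the caller concatenates them). Predicted-value animation uses 17
frames over the observed predictor range with covariates held at
reference values (means for continuous, modes for factors); the
instantaneous rate of change is the central finite difference of those
frames (one-sided at the ends), exact for linear trajectories.

Geometry displays: the "closest region" query returns the vertex's ROI
label (nearest labeled vertex for unlabeled ones) plus the region's
outline (its vertices with a differently-labeled neighbor).
"Geometry as a predicted variable" displaces vertices along
area-weighted vertex normals by the mean-centred predicted map times a
user scale — a deliberately simple, pure-function stand-in for a
biomechanical deformation model, chosen so that constant maps leave the
mesh unchanged and displacement is linear in the map. PNG snapshots
use an orthographic software z-buffer rasterizer with fixed camera
presets (superior/inferior/lateral/medial), Gouraud-interpolated vertex
colors and alpha-0 background, so identical inputs give byte-identical
files.

## Genotype handling

PLINK 1.x binary trios are decoded and encoded directly from the
published 2-bit SNP-major layout (00 = hom allele1, 01 = missing, 10 =
het, 11 = hom allele2, subjects packed 4 per byte, low bits first).
Coordinates are 1-based and ranges are closed intervals, matching bim
conventions and inclusive gene-range displays. Allele exports write
two-letter pairs (allele1 doubled, allele2 doubled, heterozygotes in
alphabetical order, missing "00") keyed by subject id, so the file
merges back into the cohort as a user spreadsheet. Exports are charged
against a cumulative per-project ledger (default cap 1000 SNP columns,
configurable); a request over the cap is refused without touching the
ledger, and whole-matrix export is refused regardless of quota.

## The synthetic cohort

The generator emulates the *structure* of a multi-site developmental
imaging-genetics study, not any real study's values. Defaults: n = 800
subjects, one visit each, ages uniform on [3, 21] years, balanced
gender, 10 acquisition sites with N(0, 250 mm²) device offsets, K = 5
Dirichlet(0.5) ancestry factors, ordinal income and education on 1–5
with 800 and 300 mm²/level slopes and 5% missingness (to exercise
listwise deletion), ICV ~ N(1.45·10⁶, 1.2·10⁵) mm³ entering at 0.02
mm²/mm³, and Gaussian residual noise of 4000 mm².

The total-area age trajectory is a gamma-density-shaped curve
amplitude·(a/p · e^{1−a/p})^4 peaking at p = 9.5 years for boys and
10.5 for girls (amplitude 15 000 mm², baseline 170 000 mm²), plus an
additive male offset of 500 mm² — smooth, unimodal, GAM-recoverable,
and encoding the qualitative pattern that boys peak earlier and decline
faster. Because the gender difference is partly curve-shaped, the
truth sidecar stores the *realized* recovery target for the gender
main-effect coefficient (the male–female gap averaged over the sampled
male ages), not the bare offset.

Hemisphere meshes are subdivision-3 icospheres (642 vertices, radius
50 mm) with octant-based ROI labels; vertex area-expansion measures are
1.0 plus noise (sd 0.08) everywhere except one labeled patch
("precentral", 93 vertices per hemisphere) which carries the age curve
at amplitude 0.25 peaking at age 10 — giving vertex-wise tests a known
localized effect and a known peak age. Genotypes are Hardy–Weinberg
draws at uniform(0.05, 0.5) minor-allele frequencies; three SNPs sit
inside the SHH gene range and three inside STON2 in the bundled gene
table, and SNP effects on area default to zero (null covariates).

What the generator does **not** emulate: real effect sizes or
covariances between measures, site-by-age confounding, non-Gaussian
measurement error, spatially correlated vertex noise, linkage
disequilibrium, or population stratification linking genotypes to
ancestry factors. Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the generating model, not
robustness to the messiness of real cohort data.

## Problem sizes and tolerances

Tests and the acceptance script run at deliberately desk-friendly
sizes: the default n = 800 cohort, 642-vertex hemispheres, 500 SNPs,
200 null replicates for FDR calibration, 100 random matrices for PLINK
round-trips, 1000 random vectors/queries for the BH and range-query
oracles, and 50 replicates at n = 200 for the AIC power study. Exact
algebraic contracts (OLS equivalence, PLINK round-trip, BH oracle) are
asserted to 1e-8 or exactly; stochastic recoveries use 3-standard-error
or 3-Monte-Carlo-SE bands. One test cross-checks the penalized smooth
fit against the R mgcv implementation on a small fixture and is skipped
cleanly where R is unavailable.

## Known limitations

- Per-term p-values for penalized smooths are approximate (see above).
- A single shared smoothing weight per model; no per-term λ vector.
- No multiple imputation: listwise deletion is the only missing-data
  policy.
- Cross-sectional models only; repeated visits are detected and warned
  about, not modelled.
- The normal-displacement geometry deformation is a visualization
  device, not a growth model.
- The QC author field is free text; there is no user/role system.
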