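# Methods

This note documents the models implemented in `covgrad`, the synthetic
data they are validated on, the numerical conventions, and the design
choices made where conventions in the field diverge.

## Synthetic geometry

A real analysis runs on a parcellated cortical surface with spherical
registration coordinates. The stand-in is an icosphere (trimesh,
subdivision level configurable; level 4 gives 2,562 vertices) split into
left/right hemispheres at the x = 0 plane. Parcels are Voronoi cells of
a randomly rotated Fibonacci lattice, refined by up to 25 Lloyd
relaxation sweeps per hemisphere with empty-cell repair (an empty cell's
seed jumps to the worst-covered vertex). Lloyd refinement is needed
because cells clipped by the medial wall or the hemisphere boundary
would otherwise be badly unbalanced; after refinement parcel
vertex-counts vary by well under a factor of 3. Two polar caps (angular
radius 0.25 rad) emulate a medial wall and are excluded from every
parcel. Per hemisphere, two antipodal-ish vertex sets near the
(medialized) directions (±0.15, −0.4, +0.9) and (±0.15, +0.4, −0.9)
serve as archicortical and paleocortical origin seeds for dual-origin
analyses. Communities (default 7, emulating functional networks) come
from k-means on parcel centroids. Everything is deterministic given the
seed.

## Planted ground truth

Two orthogonal spatial axes — the y (posterior-anterior) and z
(inferior-superior) centroid coordinates, standardized — generate
squared-exponential kernels K(g) = exp(−Δg²/2ℓ²). Genetic and
environmental correlation matrices are kernel mixtures

    C = (w1·K(g1) + w2·K(g2) + u·I) / (w1 + w2 + u),

each with its own weights and length scale, and the covariances are
scaled as sigma_g = h2_mean·σ²p·C_g and sigma_e = (1−h2_mean)·σ²p·C_e, so
the planted per-parcel heritability is exactly h2_mean. (An equivalent
parameterization scales the kernel mixture directly; the correlation
normalization is used so heritability levels can be planted exactly.)
Defaults: h2_mean 0.5, w1 1.0, w2 0.5, ℓ 0.5 (axis SD units), unique
weight 0.3, environmental weights 0.4/0.4 with ℓ 0.8, phenotypic SD
0.15 mm around a 2.5 mm baseline — values chosen once to resemble
parcel-level thickness statistics in young-adult cohorts. A helper
plants exact pairwise (h²ᵢ, h²ⱼ, ρg, ρe) for two-parcel recovery
studies.

Cohorts contain MZ/DZ twin pairs (always 2 members) and singletons.
Additive values are a ~ MVN(0, sigma_g) with cross-twin correlation 1
(MZ) or 1/2 (DZ, via a₂ = a₁/2 + (√3/2)·a'), environmental deviates
MVN(0, sigma_e) independent per subject; thickness = baseline + age, sex
and site effects + a + e. Covariates: age ~ U(22, 37) shared within a
pair, sex ~ Bernoulli(1/2) (shared for MZ pairs), site uniform over a
configurable number of labels; effect sizes are small spatially varying
slopes (≈ −0.002 mm/yr, 0.02 mm for sex) stored in the ground truth.
All randomness flows through one seeded generator; a 1e-8·σ² jitter is
added before Cholesky factorization.

What the generator does **not** emulate: vertex-level scanner noise,
non-additive genetics (dominance, shared environment), extended
pedigrees, age-nonlinear maturation, or hemispheric asymmetries of real
cortex. Passing tests therefore demonstrate correctness of the
estimators under the additive twin model, not robustness to every
violation real data can present.

## Structural covariance

Vertex values aggregate to parcels by a 10% trimmed mean (per parcel,
drop ⌊0.1·m⌋ smallest and largest of m values; stable sort, symmetric
drop counts). Covariates are removed by per-parcel OLS with intercept;
two presets are shipped — (age, sex, global thickness) for covariance
analyses and (age, sex, age², age×sex, global thickness) for the
variance-component analyses — plus an optional site factor. Global
thickness is the per-subject mean over parcels. Structural covariance is
the Pearson correlation of residuals across subjects. Note that removing
global thickness deliberately changes the correlation structure (it
absorbs the shared component), so recovery studies that compare against
the planted matrices residualize age and sex only.

Community structure is tested by comparing each community's mean
within-community off-diagonal value against a null built by permuting
parcel labels (community sizes preserved), one-sided
p = (1 + #{null ≥ obs})/(n_perm + 1), with Benjamini–Hochberg FDR across
communities. Subjects whose absolute hemispheric mean-thickness
difference exceeds 0.2 cm are excluded by the QC rule.

## AE variance components

The G+E (AE) model is fit by maximum likelihood on the Gaussian pair
likelihood — exact for twins plus singletons. Traits are residualized
and inverse-normal transformed upstream (Blom offset: ranks to
Φ⁻¹((r − 3/8)/(n + 1/4)), average ranks on ties), then centered and
ML-standardized; means are fixed at zero thereafter.

*Univariate:* the likelihood depends on the data only through per-group
sums of squares and cross-products, and the scale profiles out in closed
form, leaving a 1-D problem in h² solved by a 41-point grid plus bounded
refinement (tolerance 1e-8). h² is constrained to [0, 1]; the MZ pair
covariance is kept invertible by evaluating at h² ≤ 1 − 1e-10.

*Bivariate:* the 4-variate pair covariance (order twin1-trait-i,
twin1-trait-j, twin2-i, twin2-j) has within-person block
[[1, ρp], [ρp, 1]] and cross-twin block r_k·[[h²ᵢ, g], [g, h²ⱼ]] with
g = ρg√(h²ᵢh²ⱼ) and r_MZ = 1, r_DZ = 1/2. A single common scale is
profiled analytically (Σ = s²·C(θ)), reducing the optimization to
(h²ᵢ, h²ⱼ, ρg, ρe), run with L-BFGS-B from two starts: a
method-of-moments start (univariate h² estimates; ρg from the MZ
cross-twin cross-trait moment; ρe from the residual of the phenotypic
correlation) and a neutral start. Function evaluations cost O(1) in the
number of families because the likelihood uses per-zygosity
second-moment matrices. Likelihood-ratio p-values for ρg = 0 and ρe = 0
use χ²₁; p-values at h² or ρ boundaries are flagged, with no 50:50
mixture correction (a documented limitation — boundary LRTs are
conservative). Pairs with h² at the zero boundary flag ρg as poorly
identified.

The all-pairs driver fits every parcel pair independently (failures are
recorded and the cell left missing) and assembles ρg/ρe/ρp matrices with
unit diagonals plus the per-pair genetic share
ρ_ph_g/ρp = √h²ᵢ·ρg·√h²ⱼ/ρp.

## Gradient decomposition

Row thresholding retains, per row, the ⌊keep_fraction·(p − 1)⌋ largest
off-diagonal entries by signed value (stable sort; ties resolve toward
the lower column index), default keep_fraction 0.10 ("90% cutoff").
The normalized-angle kernel 1 − arccos(cosine)/π is computed between the
(generally asymmetric) sparsified rows, symmetrized by averaging, and
clamped to [0, 1]. Negative entries may survive thresholding; the cosine
handles their sign and the clamp guards the boundary.

Diffusion embedding density-normalizes W_α = D^(−α) W D^(−α) with
α = 0.5, row-normalizes to a Markov operator, and eigendecomposes via
the symmetric conjugate (dense `eigh`; exact and fast at p ≤ a few
thousand). Gradients are the nontrivial right eigenvectors normalized
against the trivial constant eigenvector and scaled by λ/(1 − λ)
(diffusion time 0, the multi-scale convention of the open gradient
tools) or λ^t for t > 0. Variance explained is λᵢ over the sum of
positive nontrivial eigenvalues — a declared convention, since the
quantity has no canonical formula. Per-component signs are fixed so each
gradient correlates non-negatively with the parcel-order index (the
embedding sees only an affinity matrix, so a geometric anchor is not
available at this layer); ties fall back to a positive max-|value|
entry. A disconnected affinity graph is an error reporting component
sizes.

Binning ranks parcels along a gradient into n_bins near-equal groups
(sizes differ by ≤ 1) and averages source values within/between bins,
excluding the diagonal within bins. Gradient sets are aligned across
decompositions by greedy maximal-|r| column matching with sign
resolution.

## Spatial statistics

*Geodesic distance* uses Dijkstra on the mesh edge graph weighted by
Euclidean edge length — a graph approximation that overestimates true
surface geodesics by a few percent at icosphere resolutions; exact
polyhedral geodesics were judged unnecessary for parcel-level maps.
Distances are ipsilateral only (each hemisphere's subgraph). The
parcel-to-parcel matrix runs one Dijkstra per parcel from the vertex
nearest its centroid and averages over target-parcel vertices,
symmetrizing afterwards; the exact all-vertex-pairs average would be
O(V²) for no practical gain at this resolution.

*Spin test:* the default null applies one uniform random rotation of the
whole sphere per iteration and maps each rotated parcel to the nearest
original centroid (duplicates allowed). On this single-sphere geometry a
whole-sphere rotation is an exact symmetry of any isotropic spatial
process, and the measured type-I error sits inside [0.03, 0.07] at
nominal 0.05. The mirrored per-hemisphere variant (rotation R on the
left, M·R·M on the right, reassignment restricted ipsilaterally) — the
convention when each hemisphere is registered to its own sphere — is
available as `mode="hemisphere"`, but on a shared sphere its boundary
compression makes it measurably anticonservative, which is why it is not
the default. Two-tailed p = (1 + #{|r_null| ≥ |r_obs|})/(n_rotations+1);
default 1000 rotations.

*Energy test:* Székely–Rizzo energy distance
E = 2·mean‖a−b‖ − mean‖a−a′‖ − mean‖b−b′‖ with within-sample means over
all ordered pairs (zero diagonal included), which guarantees E ≥ 0 with
equality iff the samples coincide as multisets; permutation p by pooled
relabeling (default 1000). A −log distance potential is available as an
option; its statistic carries no sign guarantee. Size-1 samples are
allowed (their within-sample term is 0 by convention).

*Dual origin:* parcels split at the gradient median (the cut rule is a
declared choice); each origin's distance field is energy-tested between
halves, and the gradient-distance correlation is spin-tested. Pearson or
Spearman is selectable per analysis. Distance-regressed covariance
removes [1, d, d²] by OLS over all finite-distance (ipsilateral) pairs;
cross-hemisphere entries pass through unchanged. Correlation confidence
intervals use Fisher z for Pearson and a seeded bootstrap for Spearman.

## Microstructure

The equivolumetric depth fraction is evaluated exactly, with the
equal-area limit ρ = α taken when |A_out − A_in| is below 1e-9 relative.
Per-vertex areas are one-ring barycentric areas (one third of each
incident face), computed on outer/inner shells obtained by radially
offsetting the mid-surface by half the cortical thickness. Profile
sampling linearly interpolates a depth-resolved intensity field at the
equivolumetric depths of 12 surfaces (uniform volume fractions) and
averages per parcel. The synthetic intensity generator gives each
community a logistic depth-ramp template (midpoint and slope vary by
class, emulating laminar differences in a myelin-sensitive contrast)
plus white noise.

MPC computes, per subject, Pearson correlations between parcel profiles
over depths and with the cortex-wide mean profile, combines them into
the partial correlation (rᵢⱼ − rᵢc·rⱼc)/√((1−rᵢc²)(1−rⱼc²)), and
averages across subjects; plain averaging is the default with a Fisher-z
option, since the field's protocol does not specify. Cells with
|rᵢc| = 1 are NaN; the diagonal is 1 by convention. MPC matrices share
the matrix container and run through the gradient pipeline unchanged,
with the same default 90% row threshold.

## Pipeline and reproducibility

A single YAML-configurable entry point runs simulate → QC → covariance →
community test → variance components → gradients → spatial statistics,
writing TSV/CSV artifacts with JSON sidecars. The master seed fans out
to per-stage child seeds via `numpy.random.SeedSequence.spawn` (all
below 2³¹), so stages are independently reproducible and a rerun with
the same configuration is byte-identical. Configuration is validated
explicitly (range checks, unknown keys rejected). The default pipeline
fits variance components on a leading subset of parcels
(`quantgen_max_parcels`, default 20) because the all-pairs bivariate fit
scales as p²; the full matrix is available by raising the limit.

## Problem sizes used in validation

Recovery and calibration studies run at: heritability — 250+250
families, 10 parcels, 10 seeds per level (h² ∈ {0.2, 0.5, 0.8});
genetic correlation — 300+300 families, 10 seeds for the planted pair
and one 50-parcel cohort for the matrix; gradients — 200 parcels, 1000
subjects; embedding oracle — 300 parcels against a dense
independent eigendecomposition; spin/energy calibration — 500 null
replicates (99 rotations / 199 permutations each); community null
calibration — 200 replicates. These sizes give Monte-Carlo error
comfortably below the tolerances they are checked against.

## Known limitations

Twins-plus-singletons only (no extended pedigrees, household or
dominance components); boundary likelihood-ratio inference is
conservative; the graph geodesic slightly overestimates surface
distance; variance-explained fractions are convention-dependent and not
comparable across packages that normalize differently; the bivariate
fit standardizes traits and profiles one common scale rather than two
free scales (exact for exchangeable twins, an approximation otherwise).
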