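# Methods

This note documents the statistical machinery implemented in `molargm`, the
defaults it ships with, and what the synthetic tests do and do not establish
about real teeth.

## Superimposition

**Centroid size.** CS = √Σᵢ‖xᵢ − x̄‖² over all 75 points (landmarks and
semilandmarks alike). Size analyses use log CS.

**Generalized Procrustes Analysis.** Configurations are centred, scaled to
unit centroid size and rotated to a consensus that is re-estimated each
iteration; iteration stops when the RMS consensus displacement falls below
1e-6 (at most 100 iterations; non-convergence raises a warning and is flagged
on the result, never silent). Unit-size normalisation is kept throughout —
the aligned shapes all satisfy CS = 1 and zero centroid to 1e-9, and the
consensus equals the arithmetic mean of the aligned shapes. Reflections are
never allowed, because left and right molars are chiral; mirroring a right
tooth onto a left template must be done explicitly upstream. The global
orientation of the solution is fixed deterministically (consensus principal
axis along x, sign by third central moments), which makes the output
invariant to specimen input order and to similarity transforms pre-applied to
any specimen — properties the test suite checks directly.

**Tangent projection.** Before any covariance-based statistic the aligned
shapes are projected orthogonally onto the tangent space at the consensus
(the component along the consensus direction beyond the consensus itself is
removed). This is the standard small-variation treatment; for the shape
variation in these data the projection is nearly the identity, but it makes
the PCA/regression geometry exact.

## Sliding semilandmarks

Semilandmarks carry no point-wise homology along the enamel–dentine junction,
so during superimposition each may slide along the outline. The bending
energy of the thin-plate spline from the reference (the current consensus) to
the specimen is the quadratic form Σ_c d_cᵀ B d_c, where B is the K×K
bending-energy matrix of the reference (upper-left block of the inverse of
the bordered TPS system with kernel U(r) = r² log r²) and d the displacement
field. B annihilates affine displacement fields and is positive
semi-definite.

Each semilandmark's tangent is the chord through its two outline neighbours
(for semilandmarks adjacent to a fixed landmark, that landmark is the
neighbour). Writing the slid configuration as X + Uλ, with U the tangent
matrix and λ the per-semilandmark amplitudes, the minimiser
λ = −(UᵀBU)⁻¹UᵀB d₀ is solved jointly for all 66 semilandmarks — not
greedily — so the energy never increases. Sliding rounds alternate with GPA
alignment rounds (the reference is the current consensus, re-estimated each
outer round, at most 5 rounds, tolerance 1e-6). Pure linearised sliding is
the default; an optional `projected_curve` mode re-projects slid points back
onto the specimen's piecewise-linear outline for strongly curved segments.

The 66 semilandmarks are divided across the 9 inter-landmark segments as
equally as possible, the remainder going to the longest segments of the
template by arc length; the allocation is configurable because digitising
protocols differ.

## Shape statistics

**PCA** of the tangent-space coordinates; components are ordered by
eigenvalue with a deterministic sign convention (largest-magnitude loading
positive). All non-negligible components are kept so the centred data are
exactly reconstructible; variance proportions sum to one.

**Variance decomposition** ("how much shape variation does wear explain?")
is a Goodall-style Procrustes ANOVA: sequential (Type I) sums of squares of
the shape variables over one or two factors, main effects in caller order and
the interaction last, each term reported as percent of the total SS (rows
plus residual total 100). Significance is by permutation of reduced-model
residuals (Freedman–Lane) with a mandatory seed; for one factor with n ≤ 8
and enough requested permutations, the full permutation group is enumerated
and the p-value is exact. We use an SS decomposition rather than Wilks' Λ
because "percent of shape variation explained" is an SS quantity; a
parametric MANOVA on retained PC scores answers a different question and can
be run on the scores directly with statsmodels if wanted.

**Size tests.** One-way ANOVA on log CS at α = 0.05, plus all pairwise
two-sided Wilcoxon rank-sum tests — exact when both groups have n ≤ 25 and no
ties, mid-rank normal approximation with continuity correction otherwise —
adjusted over the whole pairwise family by Benjamini–Hochberg step-up.

**Allometry.** Multivariate regression of the shape variables on log CS;
R² = SS_model/SS_total over all shape variables, permutation p by shuffling
sizes against shapes.

## Classification

Principal components are retained up to 95% cumulative variance (the
smallest leading set; configurable) before any CVA, to keep discriminant
estimation honest in high-dimensional shape space. `CVA(scores, groups).fit()`
solves the between/within generalized symmetric eigenproblem; canonical axes
are scaled to unit pooled within-group variance; Mahalanobis distances
between group means use the pooled within-group covariance (shrunk toward its
diagonal with λ = 1e-8 and a warning if its condition number exceeds 1e10).

Cross-validated accuracy refits the linear Gaussian discriminant (group
means and pooled covariance) on the remaining n−1 specimens for every held-out
specimen. GPA and PCA are computed once on the full training sample — the
common practice in geometric morphometrics, which leaks a small amount of
alignment information into the folds; recomputing the full chain per fold is
possible by calling the pieces directly, and the leakage is negligible at the
sample sizes involved here (the suite verifies the LOO confusion equals a
literal refit-per-specimen oracle).

Archaeological unknowns are aligned to the modern consensus by ordinary
Procrustes (optionally slid against the consensus), tangent-projected, centred
on the modern mean shape and projected onto the modern eigenvectors; they
never influence the consensus or the eigenvectors. Priors are equal across
groups by default because archaeological base rates are unknown
(proportional-to-n priors are available). Exact posterior ties are broken
toward the first group in sorted label order and flagged.

## Neighbour-joining phenograms

Saitou–Nei neighbour joining of the Mahalanobis matrix, with deterministic
tie-breaking (lowest index pair in sorted-label order), so a given matrix
always produces the same newick string. NJ is consistent on additive
matrices — the suite verifies exact recovery of randomly generated additive
trees. Negative branch-length estimates (possible on strongly non-additive
input) are clamped to zero for display with the original values retained on
the tree object.

## Synthetic data

The generator builds a bilobed, star-shaped closed outline (two lobes plus
mild higher harmonics; never self-intersecting), places the 9 fixed landmarks
at its strongest curvature extrema and the 66 semilandmarks by equidistant
arc-length resampling per segment, and plants:

- a **wear deformation**: one fixed shape direction with magnitude
  proportional to wear class (default 0.08 Procrustes units per class), and
  multiplicative centroid-size factors non-decreasing with wear (default
  +3% per class) — worn teeth are both differently shaped and larger;
- a **subspecies offset**: ±0.03 Procrustes units along a group axis, with
  within-group biological scatter along the same axis (sd 0.029) chosen so
  the planted Mahalanobis separation is ≈2, i.e. an expected two-group
  assignment accuracy near 100·Φ(1) ≈ 84% — the middle of the plausible
  range for moderately overlapping subspecies;
- **within-group biological modes**: 5 orthogonal shape directions with sd
  0.02 each, emulating the concentration of real within-population shape
  variance in a few integrated modes rather than white landmark noise;
- **sizes**: forest reindeer base CS 16.5 mm, wild mountain 15.4 mm, domestic
  15.0 mm (forest largest, domestic smallest), males +3%, log-normal
  individual scatter (cv 0.04);
- a weak **sex shape effect** (0.005 units) and optional **allometry**;
- isotropic Gaussian **digitising noise** per landmark (sd 0.002 under the
  default design; 0.005 for bare designs).

All planted directions are drawn from the design seed, projected out of the
template's affine fields and mutually orthonormalised, so no planted effect
can be absorbed by superimposition and each contributes an independent,
predictable variance share — the planted percent-variation used by the
recovery tests follows in closed form from the magnitudes. Every specimen
receives a random rotation and translation and its own centroid size, so
superimposition is genuinely exercised; a fixed seed reproduces the dataset
byte for byte.

**What the synthetic tests do not show.** The generator's effects are exactly
linear in tangent space, noise is Gaussian, and cells are balanced; real
outlines have curved shape trajectories with wear, unbalanced sex/population
cells, digitising error correlated along the outline and between operators,
and population structure beyond a single offset axis. Passing recovery tests
therefore demonstrates the correctness of the estimators under the stated
model, not field-level accuracy on real assemblages.

## Problem sizes and numerics

The acceptance checks use an 8-point toy outline (4 fixed + 4 sliding) for
Monte-Carlo recovery — 50 replicate datasets of 200 specimens for the
separation check, 20×201 for the variance-fraction check, 200×30 for the
allometry null — and the full 75-point protocol at ~100 teeth per wear class
for the study-scale run; these sizes give Monte-Carlo error well inside the
stated tolerances. Degenerate configurations (coincident points, zero-length
tangents, singular TPS kernels, constant size vectors, single-level factors)
raise typed errors naming the offending specimen or point. Permutation
p-values are never below 1/(n_perm+1); seeds are mandatory and recorded in
every report.

## Known limitations

- TPS "curves" records (`CURVES=`/`POINTS=`) are not parsed; only flat
  landmark lists.
- Coordinates are used as stored (y-up, no image-axis flip); left/right
  mirroring must be explicit.
- Specimens lacking a SCALE factor are flagged unit-unknown and should be
  excluded from size analyses by the caller; shape analyses are unaffected.
- The wear deformation model is linear in wear class; ordinal non-linearity
  in real wear is only captured by stratifying analyses per class.
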