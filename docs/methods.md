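# Methods

## Superimposition and the symmetry decomposition

Configurations are superimposed by generalized Procrustes analysis: each
shape is centered, scaled to unit centroid size and rotated (proper
rotations only, det +1) to the running consensus; the consensus is the
plain mean of the aligned shapes and iteration stops when it moves by less
than 1e-10 (root-summed-squared), with a 200-iteration cap and a
non-convergence flag on the result. Statistics downstream use the
Procrustes coordinates directly (no separate tangent-space projection):
shape variation in these applications is small relative to the curvature
of shape space, and this matches common practice in landmark-based skull
studies.

Object symmetry is handled by reflecting each configuration (negating the
first coordinate — the choice of axis is immaterial because the joint fit
re-rotates everything; it is fixed for reproducibility) and swapping the
labels of bilateral landmark pairs. Originals and mirrored copies are
superimposed jointly, and the consensus is symmetrized each iteration,
which pins the symmetry plane of the fit to the x = 0 coordinate plane so
that reflect-and-relabel acts as an exact involution on fitted shapes. The
symmetric component of a specimen is the mean of its aligned original and
aligned mirrored copy; the asymmetric component is the aligned original
minus the symmetric component, making the reconstruction identity exact by
construction (verified to machine precision rather than bitwise, since
floating-point addition does not guarantee `s + (a - s) == a`).

Measurement error uses a two-level Procrustes ANOVA (individuals +
digitization residual). Sums of squares are taken over all shape
coordinates of the chosen component — full Procrustes coordinates by
default, configurable to the symmetric or asymmetric component, since
conventions differ between software packages. Degrees of freedom carry a
shape-dimension multiplier of 3k − 7 (translation 3, rotation 3, scale 1);
repeatability R = s²_ind/(s²_ind + s²_err) with s²_ind = (MS_ind −
MS_err)/r is invariant to that multiplier, which therefore only affects
the reported df, not the statistic. Specimens lacking the modal replicate
count are excluded with a logged count.

## Ordination, classification, group tests

PCA is the eigendecomposition of the covariance matrix of column-centered
shape coordinates (denominator n − 1 everywhere in the package); ties in
eigenvalues are broken by stable sort on the original axis index. The
broken-stick retention rule keeps the initial run of axes whose variance
share exceeds b_i = (1/p)·Σ_{j=i..p} 1/j; with all eigenvalues equal it
retains zero axes (b_1 = H_p/p > 1/p for p > 1).

Shape data are rank-deficient after superimposition, so the CVA operates
in the principal-component subspace of non-zero variance, additionally
capped at n − g − 1 dimensions in the pipeline so the pooled within-group
covariance stays invertible. Mahalanobis distances between group means use
the pooled within-group covariance; their permutation test shuffles group
labels and counts permuted distances at least as large as observed, with
the observed statistic included in numerator and denominator (so p ≥
1/(n_perm + 1), a convention used by every permutation test in the
package). Cross-validated classification is a linear discriminant fitted
on training folds only; leave-one-out is the default (deterministic,
appropriate at these sample sizes), stratified k-fold is available. Cohen's
kappa is computed from the confusion-matrix marginals.

Pairwise PERMANOVA uses the pseudo-F from Euclidean distance matrices,
F = (SS_b/(g−1))/(SS_w/(n−g)), with sums of squares obtained from squared
pairwise distances (Gower identity). By default the distances come from
all PCs with non-zero variance, which makes them equal to full shape-space
distances (an orthonormal rotation preserves Euclidean distance); a
broken-stick cutoff is available by flag. Permutations shuffle specimen
labels within the pooled pair; Holm's step-down correction is applied
across the family of requested pairs (all three category pairs by
default).

## Modularity and integration

The covariance ratio is CR = ‖S₁₂‖_F / √(‖S₁₁*‖_F ‖S₂₂*‖_F) on the
(3k × 3k) covariance matrix of flattened shape coordinates from a single
Procrustes fit of the complete configuration, with the within-module
block diagonals zeroed. The permutation null reassigns whole landmarks
(x, y, z move together — the modular hypothesis is about landmarks, not
coordinates) to modules of the original sizes; p is the lower-tail share
of null CRs ≤ observed. The default null is unrestricted reassignment, the
standard null of the CR test; a spatially contiguity-restricted null
(random connected modules on a user-supplied landmark adjacency graph) is
available by flag for users who want alternative partitions confined to
anatomically coherent subsets. Default 999 permutation rounds,
overridable (main analyses in the literature often use 10,000).

Two-block PLS factorizes the cross-block covariance matrix C = X₁ᵀX₂/(n−1)
of the column-centered module blocks by SVD. Axis i carries
100·d_i²/Σd_j² percent of total covariance (Σd_j² = ‖C‖²_F); block scores
are the centered data projected on the corresponding singular vectors, and
r-PLS is the axis-1 score correlation. Vectors are oriented so the axis-1
correlation is non-negative (singular-vector signs are arbitrary). The
permutation test shuffles the specimen rows of the second block and counts
null singular values (and null |score correlations|) at least as large as
observed, per axis. Per-category analyses re-superimpose each category by
default ("refit per group"); subsetting the pooled fit is available by
flag, and the pooled-vs-refit choice changes per-category r-PLS only
mildly on synthetic data.

Axis-vector comparisons fold angles to [0, 90] degrees via the absolute
cosine, because PC/PLS vector signs are arbitrary. The analytic null for
the angle between independent uniformly distributed unit vectors in d
dimensions uses cos²θ ~ Beta(1/2, (d−1)/2); d is the number of shape
variables of the component being compared, not the specimen count, since
the vectors live in variable space. A Monte-Carlo null is available and
agrees with the analytic form to < 0.005. When per-group PLS vectors are
compared across groups, each block vector is embedded (zero-padded) into
the pooled variable space first so the vectors are commensurable.

Matrix correlation between two covariance matrices of the same landmark
configuration is the Pearson correlation over corresponding entries taken
blockwise by landmark (all nine entries of each off-diagonal 3×3 landmark
block, upper block-triangle; the six upper entries of diagonal blocks when
included — included by default, excludable by flag). The null permutes the
landmark order of the second matrix, moving whole 3×3 blocks.

## The synthetic generator

`simulate_dataset` emulates a cross-sectional sample of adult crania with
artificial deformation categories. Its template is a stylized,
mirror-symmetric 31-landmark cranium in mm (centroid size ≈ 400); an
8-landmark toy schema exists for fast tests. Defaults are fixed once as
the package's study conditions:

- sample sizes 74 / 118 / 77 (antero-posterior / non-deformed / oblique);
- antero-posterior deformation: the braincase is compressed along the
  antero-posterior axis by 8% with compensatory lateral expansion that
  preserves centroid size; oblique deformation: posterosuperior shear of
  the braincase (0.08 rad) with centroid-size restoration. Deformation
  intensity varies between specimens (relative sd 0.5, truncated at zero),
  and non-deformed crania receive small half-normal amounts of both
  deformations — artificially deformed and non-deformed skulls form a
  morphological continuum, and this is what gives realistic group overlap
  (cross-validated accuracy ≈ 0.76-0.80, Mahalanobis distances ≈ 3-5)
  instead of trivially separable categories;
- integration: a shared cross-module factor (variance 34 mm²) and
  module-specific factors (6 mm² each) act along the same unit loading
  field within each module, so the implied cross-block score correlation
  is ρ = s/(s+v) = 0.85; `SyntheticSpec.with_target_integration(rho)`
  inverts this relation. All loading fields are constructed by alternating
  projections to be exactly module-supported *and* orthogonal to the
  similarity tangent space (translation, rotation, scale) of the template,
  so Procrustes alignment neither absorbs the signal nor leaks it across
  modules;
- asymmetry: fluctuating asymmetry is isotropic noise antisymmetrized
  under reflect-and-relabel (variance 0.8 mm² before antisymmetrization),
  plus an optional structured antisymmetric factor pair (3.4 / 0.6 mm² in
  the bundled preset, mirroring the symmetric construction) and an optional
  fixed directional-asymmetry field; symmetric individual noise is the
  symmetrized counterpart (`residual_sd` = 0.5 mm);
- digitization error: isotropic noise per replicate, sd 0.3 mm.

Deformations are applied before the stochastic terms, so group effects are
mean shifts (plus the intensity-variance term along the deformation axis),
which is what PCA/CVA/PERMANOVA assume. Identical specs (same seed)
produce byte-identical datasets.

What the generator does **not** emulate: rich multi-factor covariance
(one shared factor concentrates most covariance in PLS1/PC1, so the
synthetic PC1 variance share and PLS1 covariance share are higher than
real cranial data show), spatially autocorrelated digitization error,
allometry, sexual dimorphism, missing landmarks, and shared structure
between the symmetric and asymmetric covariance patterns (the synthetic
symmetric-vs-asymmetric matrix correlation is near zero; the
matrix-correlation machinery is validated by its own simulations with
shared generative structure instead). Passing tests therefore demonstrate
correctness of the estimators and calibration of the tests under the
stated factor model, not realism of any particular empirical value.

## Numerical choices and problem sizes

Covariance denominators are n − 1 throughout. Permutation p-values always
include the observed statistic. GPA convergence 1e-10 / 200 iterations;
singular values below 1e-12 (relative) are treated as zero rank. The test
suite and the acceptance script run permutation tests at 199-999 rounds
and simulations at n = 60-300 specimens with 10-50 replicates per
calibration check — sizes at which every check completes in seconds to a
couple of minutes while keeping binomial confidence regions informative.
Larger rounds (10,000) are a one-flag change in the pipeline config.

## Known limitations

- Matching (paired-object) symmetry is out of scope; only object symmetry
  is implemented.
- The measurement-error ANOVA does not separate directional-asymmetry
  terms (side, side × individual); those live in the symmetric/asymmetric
  decomposition instead, which is appropriate when replicates are
  intra-observer re-digitizations.
- The CVA reports distances in the rank-guarded PC subspace; with very
  small samples the cap n − g − 1 discards high-order variation, and
  Mahalanobis distances are then conservative.
- No missing-landmark estimation: records must be complete.
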