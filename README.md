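# craniomorph

Geometric-morphometrics analysis of **morphological integration and
modularity in the human skull**, built around 3D cranial landmark data with
object symmetry. The package is aimed at biological anthropologists and
morphometricians who want to test whether the braincase (neurocranium) and
facial skeleton (viscerocranium) behave as semi-independent developmental
modules, and how strongly the two covary — for example across crania that
were artificially deformed in infancy (antero-posterior or oblique styles)
versus non-deformed crania.

## What it computes

Given configurations of *k* 3D landmarks (the standard 31-landmark cranial
schema is built in: 11 midsagittal points plus 10 bilateral pairs, split
into 9 viscerocranial and 22 neurocranial landmarks):

- **Generalized Procrustes analysis with object symmetry.** Each
  configuration is superimposed jointly with its reflected-and-relabeled
  copy; shape variation splits into a *symmetric* component (left-right
  average; among-individual, "static" variation) and an *asymmetric*
  component (fluctuating asymmetry; "developmental" variation), with
  symmetric + asymmetric = aligned shape exactly.
- **Measurement error.** A Procrustes ANOVA of duplicate digitizations
  yields repeatability R = s²_ind / (s²_ind + s²_err) with
  s²_ind = (MS_ind − MS_err)/r for r replicates.
- **Ordination and group tests.** PCA with broken-stick axis retention
  (retain axis i while λ_i/Σλ exceeds b_i = (1/p)·Σ_{j≥i} 1/j); CVA with
  permutation-tested Mahalanobis distances; leave-one-out (or k-fold)
  cross-validated LDA classification (accuracy and Cohen's κ); pairwise
  PERMANOVA with pseudo-F = (SS_b/(g−1))/(SS_w/(n−g)) on Euclidean
  distances from PC scores, Holm-corrected.
- **Modularity: the covariance ratio.**
  CR = ‖S₁₂‖_F / √(‖S₁₁\*‖_F·‖S₂₂\*‖_F), where S₁₂ is the between-module
  block of the shape covariance matrix and S₁₁\*, S₂₂\* the within-module
  blocks with zeroed diagonals. CR ≪ 1 indicates modularity; significance
  comes from a landmark-reassignment permutation null (lower tail).
- **Integration: two-block partial least squares.** SVD of the cross-block
  covariance matrix of the two modules within a single Procrustes fit.
  Per axis: singular value d_i, % total covariance 100·d_i²/Σd_j², and the
  correlation of paired block scores; **r-PLS** is the axis-1 score
  correlation. Permutation tests shuffle specimens of one block.
- **Comparing covariation patterns.** Angles between PC and PLS axis
  vectors with an analytic null (cos²θ of independent uniform unit vectors
  follows Beta(1/2, (d−1)/2)); element-wise matrix correlation between
  covariance matrices, tested by permuting landmark order at the 3×3-block
  level.
- **Synthetic data.** A generator that emulates artificial cranial
  deformation: mirror-symmetric cranial template, per-group deformation
  fields (antero-posterior compression with compensatory lateral expansion;
  oblique posterosuperior shear), a shared cross-module factor whose
  variance sets the integration level (ρ = s/(s+v)), module-specific
  factors, directional and fluctuating asymmetry, and replicate
  digitization noise — so the whole chain is testable with no external
  data.

I/O covers TPS (`LM3=`), Morphologika-style text and two CSV dialects, with
1-based landmark indices in all files and configs.

## Worked example

```python
import craniomorph as cm

spec = cm.reference_cohort_spec(seed=42)          # 74 / 118 / 77 crania
dataset = cm.simulate_dataset(spec)
sym, part = cm.cranial31_symmetry(), cm.cranial31_partition()

fit = cm.gpa_object_symmetry(dataset, sym)
X = fit.component_matrix("symmetric")

cr = cm.cr_permutation_test(X, part, n_perm=999, seed=0, component="symmetric")
print(cr.summary())

pls = cm.pls_permutation_test(X, part, n_perm=999, seed=0, component="symmetric")
print(pls.summary(max_axes=3))
```

prints

```
Covariance ratio test of modularity
  component:   symmetric
  scope:       all
  CR observed: 0.5787
  p (null CR <= observed): 0.001
  permutations: 999

Two-block partial least squares
  blocks:    viscerocranium vs neurocranium
  component: symmetric   scope: all
  r-PLS (axis 1 score correlation): 0.6637
  permutations: 999
axis  singular_value  p_singular  percent_total_covariance  correlation  p_correlation
PLS1         0.00025       0.001                  77.09556      0.66367          0.001
PLS2         0.00013       0.001                  21.25945      0.62489          0.001
PLS3         0.00004       0.001                   1.63633      0.80899          0.001
```

CR = 0.58 with p = 0.001 rejects the hypothesis of no modular structure
(observed between-module covariation is low relative to random landmark
partitions of the same sizes), while r-PLS = 0.66 (p = 0.001) shows the two
modules nevertheless covary strongly — modularity and integration are
matters of degree, not alternatives. PLS1 carries 77% of the total
between-block covariance.

The same chain is available end to end from the shell:

```bash
craniomorph simulate --seed 42 --out crania.csv
craniomorph run --config analysis.yaml --out results/
```

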