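# beetlemorph

Geometric morphometrics of beetle dorsal outlines: a reusable pipeline
for analyzing the shapes of the **pronotum** (the dorsal plate of the
first thoracic segment) and the **elytron** (the hardened forewing)
across a family-scale sample of beetle species, and for reconstructing
the ancestral "groundplans" of those structures on a phylogeny.

The package is aimed at systematists and evolutionary morphologists who
digitize outline curves from specimen images (tpsDig-style TPS files),
want family-level answers — do subfamilies differ in shape? is
morphological disparity coupled to species richness? what did the
common ancestor look like, and which living group does it most
resemble? — and need every number to be reproducible from a seed.

## What it computes

Given one outline curve per structure per species, resampled to *k*
semilandmarks equally spaced by arc length (defaults: 25 for the
pronotum, 50 for the elytron):

- **Generalized Procrustes analysis (GPA).** Each configuration
  `X_i ∈ R^(k×2)` is translated to zero centroid, scaled to unit
  centroid size `CS(X) = √Σ‖x_j − x̄‖²`, and rotated (proper rotations
  only) to an iterated consensus `X̄`; statistics operate on the
  orthogonal tangent-space projections at `X̄`.
- **Morphospace ordination.** PCA of the tangent coordinates
  (covariance, divisor *n*−1), with per-group 90% equal-frequency
  ellipses: the covariance ellipse scaled by `√χ²₂(0.90)`.
- **Group discrimination.** Pairwise Mahalanobis distances
  `D = √(δᵀW⁺δ)` (pooled within-group covariance `W`, pseudo-inverted
  in its retained eigenbasis), canonical variate analysis, partial
  Procrustes distances between group mean shapes, and permutation tests
  (default 10000 rounds, `p = (#{null ≥ obs}+1)/(rounds+1)`).
- **Disparity vs richness.** Per-group Procrustes variance
  `V = Σᵢ d²(xᵢ, x̄_g)/(m−1)` in the global alignment, correlated with
  described-species counts (Pearson *r*, two-sided *t* on *n*−2 df).
- **Ancestral shapes.** Squared-change parsimony on a rooted tree with
  equal branch lengths — internal states minimize `Σ_edges ‖Δ‖²`,
  solved exactly via a sparse linear system — plus
  nearest-extant-group tables under both distance metrics,
  length-to-greatest-width ratios, and thin-plate-spline deformation
  grids (`U(r) = r² log r²`).
- **Synthetic data.** A generator that emulates the study design:
  parametric pronotum/elytron-like outlines, Brownian-motion divergence
  of group mean shapes along a 14-taxon tree, per-group dispersions
  planted independently of richness, TPS/Newick/CSV emission, full
  ground truth, bit-reproducible from a seed.

## Worked example

Run the whole analysis on the synthetic study-like preset (14 groups:
4 ingroup subfamilies with 47/11/1220/25 described species, 10 outgroup
families; 50 species sampled per group at most):

```sh
beetlemorph run-all --out run --simulate --seed 42 --rounds 999 --no-figures
```

or equivalently in Python:

```python
from beetlemorph import RunConfig, run_pipeline
run_pipeline(RunConfig(out_dir="run", simulate=True, seed=42,
                       rounds=999, cap=50, figures=False))
```

Selected output (`run/*.csv`, seed 42):

- `pronotum_eigenvalues.csv` — PC1 and PC2 carry 70.4% and 19.0% of the
  tangent-space variance (89.3% together; elytron: 79.7%).
- `pronotum_disparity_subfamily.csv`:

  | group | n_species | procrustes_variance |
  |---|---|---|
  | Aesalinae | 47 | 0.0148 |
  | Lampriminae | 11 | 0.0030 |
  | Lucaninae | 1220 | 0.0112 |
  | Syndesinae | 25 | 0.0096 |

  The species-poorest subfamilies are not the least disperse: Aesalinae
  (47 spp.) ranks first while Lucaninae (1220 spp.) ranks second —
  disparity decoupled from richness, exactly as planted by the
  generator.
- `pronotum_richness_correlation.csv` — across 17 sampled genera,
  *r* = 0.26, *p* = 0.31: no significant genus-level coupling.
- `pronotum_pairwise.csv` — every ingroup subfamily pair separates
  under the Procrustes-distance permutation test (all *p* ≤ 0.045 at
  999 rounds); e.g. Aesalinae vs Lucaninae: *d*_P = 0.160,
  *D* = 6.95, both *p* = 0.001.
- `pronotum_node_affinity.csv` — each reconstructed internal node is
  assigned its nearest extant group under both metrics (e.g. the
  ingroup stem node11 is nearest Diphyllostomatidae by Procrustes
  distance at this seed); `elytron_length_width_ratios.csv` reports the
  reconstructed ancestors' length-to-width ratios (root: 1.51).

A `manifest.json` records every parameter and a SHA-256 checksum of
every table; rerunning with the same seed reproduces all CSVs
byte-for-byte.

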