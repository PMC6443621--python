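# Methods

This note documents the statistical procedures implemented in
beetlemorph, the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Outline processing

A digitized outline is an ordered polyline (a TPS curve). Resampling
places *k* semilandmarks at equal *chord-length* intervals along the
piecewise-linear interpolant — positions `i·L/(k−1)` for total length
*L* — with the source endpoints preserved exactly. Chord length rather
than a spline fit is used because it is the behavior of the digitizing
tools this format comes from and it is exactly reproducible. Defaults
are k = 25 (pronotum) and k = 50 (elytron). Curves are treated as open
arcs; there is no start-point search and **no semilandmark sliding** —
resampled points become fixed landmarks, so every downstream statistic
is a deterministic function of the digitized curve. Converting a
curve-bearing TPS record to a landmark-only record concatenates all
curve points in curve order then point order.

## Superimposition

Generalized Procrustes analysis: every configuration is centered,
scaled to unit centroid size, and rotated to the current consensus by
the SVD solution restricted to proper rotations (determinant +1;
reflections are excluded because all specimens are digitized in the
same dorsal orientation, and an improper fit could silently flip a
near-symmetric outline). The consensus is re-estimated as the
renormalized mean and the loop stops when its RMS shift falls below
`tol = 1e-8` (cap 100 iterations; the flag `converged` records
failure). The consensus is initialized from the first configuration
and, on exit, rotated to a canonical orientation (major principal axis
along +x, sign fixed by the largest-magnitude coordinate). The
canonical orientation makes the aligned coordinates *invariant* — not
merely equivariant — under similarity transforms of the inputs, which
is what the invariance tests assert.

Tangent-space coordinates are the orthogonal projection of the aligned
(unit-size) shapes onto the hyperplane orthogonal to the consensus
direction; the consensus maps to the zero vector. Orthogonal (rather
than stereographic) projection is the common default of the software
lineage this analysis follows; at the dispersions involved the
difference is far below reported precision.

`procrustes_distance` is the **partial** Procrustes distance: both
shapes at unit centroid size, optimal proper rotation, root summed
squared differences. There is no extra per-shape scaling factor in the
distance, matching the fixed-unit-size convention above.

## Ordination and ellipses

PCA uses the sample covariance (divisor n−1) via SVD of the centered
data. Eigenvector signs are fixed by making the largest-magnitude
loading of each axis positive — eigenvectors are sign-ambiguous and a
deterministic rule is required for byte-reproducible outputs. The 90%
equal-frequency ellipse of a group's 2-D scores is the mean-centered
covariance ellipse scaled by `sqrt(chi2.ppf(coverage, 2))`; under
bivariate normality its empirical coverage converges to the nominal
level, which the tests check at n = 10² … 10⁴.

Reconstructed ancestors are placed in morphospace by **pooling** their
tangent rows with the extant data and refitting the PCA (the
phylomorphospace tables), with `project_into` available to project them
into the extant-only ordination instead. The joint fit is the default
because mean-shape tables and node tables are then directly comparable
in one coordinate system.

## Group discrimination

Procrustes-aligned 2-D data are rank-deficient: 4 degrees of freedom
(two translations, rotation, scaling) are removed, so all
covariance-based statistics operate in the retained eigenbasis of the
pooled within-group covariance — eigenvalues above `1e-9 · λ_max`.
Mahalanobis distances use the pseudo-inverse restricted to that basis;
canonical variates are computed in the whitened retained space, which
makes the pooled within-group covariance of canonical scores exactly
the identity and, for two groups, makes the squared separation of the
group mean scores equal D². Pairwise tests use the pair's own pooled
covariance (two-group discriminant analysis); the alternative —
covariance pooled over all groups — is available through
`pooled_within_covariance` directly.

Permutation tests permute group labels freely (group sizes preserved)
and report the add-one estimator `p = (#{null ≥ obs}+1)/(rounds+1)`,
never exactly zero. The default is 10000 rounds, seeded (package
default seed 20190325). For the pairwise tables the two statistics are
(i) the norm of the tangent mean difference — the partial Procrustes
distance between mean shapes to first order at the consensus — and
(ii) the two-group Mahalanobis form, computed against the pair's
*total* covariance via the Sherman–Morrison identity
`D² = (n−2)·q/(1−cq)`, `q = δᵀT⁺δ`, which is a monotone function of
the permutation-invariant-basis statistic `q` and lets all rounds be
evaluated as one matrix product.

Small-sample caveat: with a group of ~10 members in a ~50-dimensional
shape space the Mahalanobis permutation test has little power (the
within-group covariance is overfit and the null adapts accordingly);
the Procrustes-distance test is the informative one in that regime, and
the two can legitimately disagree.

## Disparity and richness

A group's disparity is its Procrustes variance: the summed squared
tangent-space deviations from the group mean divided by m−1, computed
**in the global alignment** (groups are not re-superimposed, so
disparities are comparable across groups and the total variance
decomposes into within- plus between-group parts). `ddof=0` is
available for cross-software comparison. Groups with a single sampled
member are excluded, and the genus-level correlation keeps only genera
with more than one described species. The richness correlation is a
plain Pearson r on raw counts with the two-sided t-test on n−2 degrees
of freedom; `log_richness=True` switches to log10 counts.

## Ancestral reconstruction

Squared-change parsimony with a free root: internal states minimize
`Σ_edges ‖x_parent − x_child‖²/ℓ_edge`. The stationarity conditions are
linear (each internal node is the branch-weighted mean of its
neighbors), assembled as a sparse graph-Laplacian system and solved
exactly per coordinate — no iteration, unique solution. Equal branch
lengths (ℓ = 1, the same expected change on every branch) are the
default; a tree's own lengths can be requested. Because the estimator
is linear in tip data it commutes with rotation and with linear
combinations, which the tests verify at 1e-10.

The consistency experiment fixes the **tree height** and varies tip
count (branch length = height/depth on balanced trees): at a fixed
rate per edge, deeper trees accumulate more root-to-tip variance and
root error does not shrink, whereas at fixed height denser sampling
averages away Brownian noise and the 64-tip root error drops below the
8-tip error. The fixed-height design is the meaningful consistency
question (same evolutionary time, better taxon sampling).

Node-versus-extant affinities report, for every internal node, the
Mahalanobis distance (covariance pooled over all extant groups with ≥ 2
members) and the partial Procrustes distance to each group's mean
shape. The two metrics answer different questions (statistical
atypicality vs absolute shape difference) and may disagree; both
nearest groups are reported and exact ties are joined with `|` rather
than broken silently. The length-to-width descriptor aligns a
configuration to its own principal axes and takes the ratio of the
bounding extents — the only label-free proxy for anatomical
length/width.

## Thin-plate splines

Standard 2-D interpolating spline with kernel `U(r) = r² log r²`,
`U(0) = 0`; exact at the landmarks, affine part separated, bending
energy the kernel quadratic form of the non-affine weights (zero iff
the target is an affine image of the reference). Deformation grids
default to 20 × 20 cells over the reference bounding box enlarged by
20%. A collinear reference makes the system singular and is rejected
with a dedicated error.

## Synthetic generator

The generator stands in for image-digitized data and defines the study
conditions end to end.

**Base outlines.** Tapered superellipses opened at a midline gap:
`shoulder` is the superellipse exponent (larger = squarer "shoulders"),
`taper` narrows the apex, `gap` sets the opening. The elytron default
targets a length-to-greatest-width ratio of 1.571 (hit to well within
1%); the pronotum default is squatter (ratio 1.30, shoulder 3.0).
Symmetric parameters yield outlines exactly symmetric about the
midline.

**Shape variation.** All perturbations act in the shape tangent space
at the base (orthogonal to translation, rotation and scaling), through
a fixed bank of smooth modes: sinusoids along the outline,
Gram–Schmidt-orthonormalized against the similarity directions, with
mode j carrying weight ∝ (j+1)^(−1.5) normalized so the total variance
equals that of an isotropic draw, `(2k−4)σ²`. Smooth modes make
neighboring semilandmarks co-vary, as in real outlines, and concentrate
variance in few directions (PC1–2 of a generated dataset carry ~70–90%,
the level real outline data show). The expected squared root-to-tip
tangent distance of a Brownian simulation is therefore
`(2k−4)·rate·depth`, which the variance oracle tests at 3%.

**Study-like preset.** Fourteen tree tips (a pectinate ladder of ten
outgroup families subtending the four-subfamily ingroup clade) with
described richness 47/11/1220/25 (ingroup) and 4–43 (outgroups; 1447
species in total, 1303 ingroup). Group means evolve by Brownian motion
at `bm_rate = 1e-4` per coordinate per branch. That rate was calibrated
once, by a seed-scan at design time, as the smallest scanned value at
which the preset reproduces the qualitative study pattern — every
ingroup subfamily pair significantly separated under the
Procrustes-distance permutation test at the preset's subsampled group
sizes (≤ 50 species/group) — while keeping group-mean separations
(~0.07–0.3) within sight of the real-data scale; at lower rates the
two smallest subfamilies fail to separate in a substantial fraction of
seeds purely for power reasons. Per-group dispersions realize the
planted Procrustes variances (pronotum 0.0158/0.0030/0.0111/0.0123 for
Aesalinae/Lampriminae/Lucaninae/Syndesinae; elytron
0.0044/0.0007/0.0025/0.0008; outgroups 0.008/0.002) — the
species-poorest groups are deliberately *not* the least disperse, so
disparity is decoupled from richness by construction. Genus sizes
follow a fixed long-tailed pattern (few large genera, many monotypic
ones). Specimens are written to TPS as one semilandmark curve each
under a random similarity transform (position, magnification, small
rotation), so the pipeline's superimposition does real work.
Regeneration from the same parameters and seed is bit-identical.

**What the generator does not emulate.** Isotropic-in-mode Gaussian
noise has no allometry, no asymmetry, no digitization operator error
correlated with image quality, and no model misspecification (the
reconstruction assumes exactly the Brownian model the generator
implements). Passing tests therefore demonstrate correctness of the
algorithms and calibration of the tests *under the generating model*,
not robustness to violations of it.

## Experiment designs used by the tests

- **Type-I calibration:** 500 null two-group datasets (15+15, 8-D
  standard normal), 1000 permutation rounds each; the rejection rate at
  α = 0.05 must lie in [0.03, 0.07].
- **Disparity-rank recovery:** the smallest preset group (Lampriminae,
  11 spp.) is planted with 4× the per-coordinate dispersion of all
  other groups; over 100 generated datasets it must rank first in
  disparity in ≥ 99 — the decoupling signature at a contrast the
  sampling noise cannot mask.
- **Planted-root affinity recovery:** the basal-most tip group is
  planted at 1× the within-group deviation norm from the true root
  while every other group mean drifts by Brownian motion at 3×; over
  200 replicates the reconstructed root's nearest group (Procrustes
  metric) must match the planted truth in ≥ 90%. Letting all groups
  drift freely instead produces frequent near-ties between the first
  and second nearest groups, which tests tie-breaking luck rather than
  the method.

## Numerical conventions and degenerate inputs

Coordinates are written to TPS and CSV with enough digits to round-trip
doubles (TPS: 17 significant digits; CSV: 12). All randomness flows
from explicit integer seeds through `numpy.random.default_rng`.
Degenerate inputs fail loudly with typed errors: zero-length curves,
coincident landmark configurations, singular group covariances,
collinear thin-plate references, unrooted trees, tips without shapes,
tree/taxa label mismatches (offenders listed). SCALE records in TPS
files are stored but applied only on explicit request. Eigenvector and
canonical-axis signs, consensus orientation, node labels (preorder
numbering from the root) and tie reporting are all deterministic.

## Known limitations

2-D configurations only; no sliding semilandmarks (deliberate — see
above); no resistant/weighted superimposition; ordinary PCA only (no
phylogenetic or between-group PCA); squared-change parsimony only (no
ML/Bayesian rate estimation, no fossil calibration); Pearson
correlation without phylogenetic correction for the richness analysis;
the Mahalanobis permutation test is underpowered for very small groups
in high-dimensional shape spaces (documented above); length-to-width
ratios use principal-axis extents, which for strongly curved shapes
need not coincide with anatomical axes.
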