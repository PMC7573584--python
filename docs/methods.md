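# Methods

`wingmorph` implements a landmark-based identification pipeline for
female mosquitoes: wing shape is extracted by generalized Procrustes
analysis (GPA), species and genus are assigned by linear discriminant
analysis (LDA) validated by leave-one-out cross-validation (LOOCV),
species relationships are displayed as a neighbor-joining (NJ) tree of
Mahalanobis distances with bootstrap supports, and the morphometric
picture is cross-checked against a short mitochondrial COI alignment
analysed by maximum likelihood.  This note records the model choices,
conventions and numerical details, and what the synthetic study design
does and does not establish.

## Superimposition

A configuration is k = 18 planar landmarks at wing-vein junctions.
Centroid size CS = sqrt(Σᵢ ‖xᵢ − x̄‖²) carries the size information;
shape is what survives removing translation, scale and rotation.

* Rotations are restricted to determinant +1.  All wings are from the
  same body side, so reflections would silently hide digitization
  errors rather than fix chirality.  The optimal planar rotation has
  the closed form θ* = atan2(Σ cross, Σ dot).
* GPA scales every configuration to unit CS (full superimposition, the
  convention of the R geometric-morphometrics family), initializes the
  consensus at the first configuration, and iterates rotate-all /
  re-average until the consensus moves by less than `tol` (default
  1e-8, root summed squared change; cap 100 iterations).
* The converged solution is only defined up to a global rotation.  We
  fix it deterministically: the consensus' major principal axis is
  rotated onto x, and the 180-degree ambiguity is resolved by requiring
  a non-negative third moment along x (falling back to y).  This makes
  GPA output *invariant* — not merely equivariant — under similarity
  transforms of the inputs, which downstream tests rely on.  Shapes
  that are almost isotropic or almost symmetric keep a stable but
  arbitrary orientation; mosquito wings are neither.
* Statistics operate on the orthogonal projection onto the tangent
  space at the consensus (`project=False` switches to raw Procrustes
  coordinates).  At mosquito-wing noise scales (Procrustes distances
  ≲ 0.1) the projection is numerically almost the identity.

A degenerate configuration (all landmarks coincident; CS below 1e-12 of
the sample maximum) is rejected with the offending specimen named.

## Size and allometry

Centroid sizes are compared across species by one-way ANOVA plus
pairwise t-tests with Bonferroni correction (adjusted p = min(1, m·p)
for m = g(g−1)/2 pairs).

Allometry is tested by regressing all tangent shape variables jointly
on log CS.  R² = SS_model / SS_total pooled over shape columns,
F = SS_model / (SS_resid/(n−2)), and significance comes from fully
permuting the specimen-to-size assignment (default 500 permutations,
seeded); p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm), so the smallest
attainable p at 500 permutations is 1/501 ≈ 0.002.  Two caveats are
deliberate properties of this widely used pooled test, not bugs:

* it conflates individual-level allometry with species-level size–shape
  covariation — any between-species shape structure that happens to
  align with the size ordering is counted as "allometry".  With g
  well-separated species, chance alignment alone contributes roughly
  1/(g−1) of the between-species shape variance to R²;
* consequently its permutation null is exact only when specimens are
  exchangeable.  Calibration is therefore verified on an exchangeable
  null (shapes independent of sizes, no group structure), where the
  type-I error is exact by construction.

Allometric residuals are *not* removed before classification (size
covariation is informative for identification); a sensitivity switch
is available by regressing them out manually.

## Disparity and observer error

Procrustes variance of a group is the mean squared tangent-space
distance of members to their group mean (denominator n, matching the R
convention; `ddof=1` switchable).  Observer error is assessed by
jointly re-superimposing originals plus all observer replicates in one
GPA, computing for each replicated specimen the variance across its
replicates, averaging over specimens, and comparing with the mean
per-species variance of the original specimens.  A ratio well below 1
means landmark digitization noise is small relative to the biological
signal the classifier uses.

## Classification

2k Procrustes coordinates span at most 2k − 4 dimensions, so shape
variables are first projected onto principal components with variance
above 1e-10 of the largest.  LDA then uses group means and the pooled
within-group covariance (denominator n − g) with the rule
argmax_g [ln π_g − ½ d²_Mahalanobis(x, μ_g)].  Priors default to group
frequencies (the R discriminant family's default; group sizes 14–30
make this matter at the margin), with uniform priors available.  Exact
posterior ties go to the lexicographically lowest label, with a
warning.

LOOCV refits the entire pipeline (rank reduction + LDA) on n − 1
specimens per fold; the GPA itself is *not* recomputed per fold,
mirroring a single up-front superimposition.  The leakage this admits
is negligible at n ≈ 500 (each specimen shifts the consensus by
O(1/n)); exact per-fold GPA can be run manually by subsetting.

CVA solves the generalized eigenproblem of between-group versus pooled
within-group covariance (≤ g − 1 axes); the Mahalanobis distance
between group means, under the pooled covariance, feeds the NJ tree.
Under bootstrap resampling, duplicated specimens can push the pooled
covariance rank below the retained PCA dimension; `auto_reduce` drops
trailing components until the covariance is positive definite (used by
the tree bootstrap; the plain fit keeps the strict error).

## Trees

NJ follows Saitou–Nei: join the pair minimizing
Q_ij = (r−2)d_ij − R_i − R_j (ties broken at the lowest index pair),
standard branch-length formulas, negative lengths clamped to zero
without redistribution.  On additive matrices the generating tree is
recovered exactly.  Morphometric supports resample specimens with
replacement *within species* (the distance matrix lives on species
means, so specimen resampling is what propagates sampling variance),
rebuild distances and tree, and report bipartition percentages.

## COI likelihood arm

Alignments are trimmed to their first 550 columns.  Site likelihoods
use Felsenstein pruning with per-node scaling; gaps and Ns are fully
ambiguous.  Models: JC69, K80, HKY85, each optionally with discrete
Gamma rate variation (4 equal-probability categories, category rate =
mean of its quartile bin of Gamma(α, α) — the "mean" discretization,
normalized to average exactly 1).  Base frequencies for HKY85 are
empirical counts (not ML-optimized) and count as 3 free parameters;
κ and α are optimized by bounded scalar search in log space
(κ ∈ [0.05, 100], α ∈ [0.02, 50]); branch lengths in [1e-8, 10] by
per-edge profile likelihood (the rest-of-tree partial is cached on both
sides of the edge, so each 1-D optimization is O(sites)), sweeping all
edges with a never-worsen guard.

`model_test` fits six candidates on a fixed NJ topology built from
Jukes–Cantor pairwise distances and ranks them by
AIC = 2·(branches + free parameters) − 2 lnL.  The six-model set is a
deliberate subset of the full model zoo — enough to separate
equal-rate/unequal-rate and with/without rate variation, including the
model family the COI data are expected to select.  `ml_search` starts
from that NJ tree and alternates branch-length sweeps with
nearest-neighbor-interchange moves, accepting the best strictly
improving neighbor until none improves; the search is deterministic.
Bootstrap resamples columns, reruns a reduced-effort search (one NNI
round from the full-data topology) and maps bipartition percentages
onto the full-data ML tree.

## Synthetic study design

The generator emulates the digitized-wing study the pipeline targets:
19 species from 5 genera with the published per-species specimen and
site counts (502 wings), 18 landmarks.  Structure and defaults:

| parameter | default | meaning |
|---|---|---|
| δ (`delta`) | 0.04 | per-landmark species mean displacement (shape units); genus level uses 2δ, so genera separate more than species; δ/σ_w = 8 |
| σ_w (`sigma_within`) | 0.005 | isotropic per-landmark within-species noise; yields per-species Procrustes variance ≈ 1.2–1.7 × 10⁻³, the observed order |
| σ_obs | 0.0035 | observer digitization noise (shape units, i.e. scaled by specimen CS); yields observer variance ≈ 3–5 × 10⁻⁴ |
| site offsets | σ_w/2 | shared per-(species, site) shape offset — geographically structured intraspecific variation |
| sizes | lognormal | species medians evenly log-spaced over a 2× range (largest ≈ 2× smallest), assigned to species in seeded-random order so size is not collinear with genus; within-species CV 0.08 |
| β (`beta`) | 0.3 | allometric shape displacement per unit log relative size, along a fixed species-specific direction |

`merge_pairs` makes chosen species pairs confusable: the second
species' mean is moved to within 1·σ_w (Procrustes distance) of the
first's and it inherits the first's allometric direction and median
size — sibling species with near-identical wings and sizes.  Without
the latter, the allometric displacement alone would re-separate the
pair, which is not the phenomenon being emulated.

Raw coordinates are emitted under random rotation, translation and
scaling, so the full superimposition is always exercised.  All
randomness flows from one seeded generator; the ground truth (species
mean shapes, genus map, true sizes, allometric directions) is returned
with every dataset.

What the generator does **not** emulate: anisotropic or spatially
correlated landmark noise, landmark-specific digitization difficulty
(scales on veins), missing landmarks, measurement drift between
sessions, and phylogenetic correlation of mean shapes.  Passing the
recovery tests therefore shows the pipeline is correct and well
calibrated under an idealized version of the study's variance
structure — not that real wings achieve any particular accuracy.

## Problem sizes used in tests and the results script

Simulation-based checks use deliberately chosen sizes: classification
recovery uses 19 species × 20 specimens over 50 seeds; permutation
calibration uses 500 null datasets × 500 permutations; NJ exactness
uses 200 random additive trees of 4–12 leaves; model selection uses 50
replicates of 20 taxa × 550 bp (one optimization round per candidate —
the AIC margins are two orders of magnitude larger than the
optimization slack); quartet recovery uses 50 replicates at 550 bp.
The results script runs the full 502-specimen design with 500
tree-bootstrap replicates, 50 landmark-sampling iterations and 25 ML
bootstrap replicates; function defaults keep the conventional 1000
replicates.

## Known limitations

* 2-D landmarks only; no semilandmarks, sliding, or missing-landmark
  estimation.
* The NNI + per-edge search is adequate for tens of taxa, not hundreds;
  no subtree-prune-regraft moves.
* GTR and invariant-sites models are out of scope; inputs must be
  pre-aligned.
* The pooled allometry test's null conflation (above) is inherited from
  the standard procedure it reproduces.
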