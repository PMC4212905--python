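# Methods

## Superimposition

Configurations are 2D, k ≥ 3 landmarks. GLS Procrustes superimposition
centers each configuration, scales it to unit centroid size (the
unit-centroid-size convention of the tps/geomorph toolchain, not cos(ρ)
rescaling), and iterates { rotate every configuration onto the consensus;
re-estimate the consensus as the arithmetic mean rescaled to unit centroid
size } from a consensus initialized at the first configuration. Rotations
are proper only — a reflection is never fitted; an explicit `mirror`
operation is provided for right wings digitized as such. Internally a
configuration is a complex k-vector, so the optimal rotation onto the
consensus c is multiplication by w/|w| with w = Σ conj(z)·c; this is exact
and vectorizes over specimens.

Convergence is declared when the consensus moves by less than `tol`
(default 1e-8, max 100 iterations) between iterations, measured as the norm
of the rotated consensus difference. The naive form √(2 − 2|⟨c, c′⟩|) is
mathematically identical but floors near √ε ≈ 1.5e-8 in double precision
and cannot certify a 1e-8 tolerance; the direct difference has no floor.
Non-convergence returns `converged=False` plus a warning, never a silent
pass.

A GPA solution is unique only up to a global rotation. To make outputs
deterministic and exactly invariant under per-specimen nuisance rotations,
the converged solution is rotated into a canonical orientation: the
consensus principal axis is placed on x, with the sign fixed so the
landmark farthest from the centroid has positive x. This is a labeling
choice; all downstream statistics are invariant to it.

## Tangent space and adequacy

Aligned shapes lie on the unit sphere; statistics use the orthogonal
projection onto the hyperplane tangent at the consensus,
x′ = x − (x·c − 1)c. Orthogonal (not stereographic) projection matches the
standard tps-SMALL-style diagnostic, which this package reproduces: the
no-intercept least-squares slope and the Pearson correlation of tangent
Euclidean distances against pairwise partial Procrustes distances, over all
n(n−1)/2 pairs. The distance between two unit-size shapes re-optimizes the
pair's rotation (d = √(2 − 2|⟨z_i, z_j⟩|)), so the matrix is independent of
the consensus orientation. Because a single number is conventionally quoted
for this diagnostic while two are computed, the report always carries both
slope and correlation.

## Ordination

Covariance PCA of tangent coordinates (coordinates share units, so
correlation scaling would distort shape variance). Axes with eigenvalue
below 1e-12 of the largest are dropped; variance fractions are taken over
the *total* variance. Axis signs are fixed by making the largest-magnitude
loading positive. Unknowns are excluded from the fit and only projected;
this matches the a-posteriori treatment of query specimens throughout the
package.

## Discrimination and assignment

LDA is fitted in two stages. (1) Tangent coordinates are reduced onto the
PCA basis of all non-null total variance (relative eigenvalue threshold
1e-10) — superimposition removes four degrees of freedom from 2k = 36, and
some groups are smaller than the ambient dimension, so this reduction is
what makes the pooled within-group covariance invertible without an
arbitrary ridge. (2) The symmetric-definite generalized eigenproblem of
between-group vs pooled within-group covariance is solved on the reduced
scores; eigh's B-orthonormalization directly yields score axes whose pooled
within-group covariance is the identity. The pooled estimator uses the
n − g denominator. d = min(g − 1, p) axes are retained, and Mahalanobis
distances are computed in the full d-dimensional space (no 2-axis
truncation): pairwise group comparisons only involve the component along
the centroid difference, so retaining weakly discriminating axes cannot
flip an assignment between well-separated groups.

Posteriors are pp_g ∝ π_g exp(−MD_g²/2), computed in the log domain with a
log-sum-exp guard so arbitrarily large distances underflow to pp = 0
gracefully. Priors default to group-size proportional ("equal" and explicit
vectors are supported); with the large MD gaps typical of this analysis the
choice is immaterial. Exact posterior ties break lexicographically on the
group label, so results are platform-deterministic.

Leave-one-out cross-validation refits the LDA (and priors) on every fold
but does **not** redo superimposition: per-fold GPA would change the
question from "does the rule generalize" to "does the registration".
Members of singleton groups are excluded from cross-validation (their group
would vanish from the training fold) and reported as such. Groups with one
member are otherwise allowed in fitting — they contribute a centroid but no
scatter — with a warning.

Assignment of unknowns uses one joint GPA of reference + unknowns (the
consensus includes the unknowns; a flag switches to a reference-only
consensus with OPA-aligned unknowns for sensitivity analysis, and the
report records which policy produced it). Each requested level is an
independent analysis on the reference rows; per-level winners are not
conditioned on coarser levels, but a lineage-consistency flag marks reports
whose winners are incompatible under the label co-occurrence of the
reference. A specimen missing a fine-level label inherits its nearest
coarser label as its group at that level (the rule for subfamilies without
defined tribes).

## Synthetic data

The generator emulates a broad multi-family wing reference collection. The
bundled 18-landmark template sketches an elongate bee-like forewing; it is
a fixture, not a digitized specimen. Defaults: 2 suprafamilies × 5 families
× 2 subfamilies per family × 2 tribes per subfamily × 4 species per tribe ×
4 specimens per species = 640 specimens in 40 tribes (16 per tribe, capped
at 20), mirroring a sampling design of a few species per tribe and a few
specimens per species with at most twenty specimens per tribe.

Group effects are i.i.d. Gaussian landmark displacements drawn per taxon
and accumulated down the lineage, orthogonalized against translation and
scaling of the template so their standard deviations read as *shape*
displacement in units of centroid size. Defaults (suprafamily 0.009, family
0.0036, subfamily 0.0031, tribe 0.0027, species 0.0015) decrease down the
hierarchy; individual + digitization noise is isotropic with sd 0.004 —
deliberately larger than the between-species effect, since within-species
individual variation dominating between-congener differences is exactly
the regime in which wing-shape classification is hard at the tribe level
and trivial at the suprafamily level. Under these conditions leave-one-out
hit ratios are 100% at suprafamily, high-90s with a handful of errors at
family/subfamily, and ~95–98% with tens of errors at tribe level, and
full-lineage recovery of held-out-species unknowns runs at ~97–98% — the
qualitative regime reported for real multi-family bee-wing datasets. The
effect scales were calibrated once, by simulation, to sit in that regime,
and are not tuned thereafter.

Each specimen then receives a random similarity transform (rotation
U(0, 2π), log-normal scale sd 0.3, translation U(−5, 5)²) emulating
arbitrary digitizing frames. Randomness derives from stable hashes of
(seed, taxon path), so adding a taxon never perturbs another's draws, and
changing only nuisance ranges changes raw coordinates but — superimposition
being exact for similarity transforms — leaves tangent coordinates
untouched.

`make_unknowns` draws query specimens from a chosen level's groups; with
`holdout=True` (default) the unknown carries a *fresh* species effect the
reference never saw, which is the honest analog of assigning a fossil of an
extinct species. Held-out unknowns are measurably harder than unknowns from
sampled species (roughly twice the error rate in our simulations), because
no training specimen pulls their group centroid toward them.

What the generator does not emulate: unbalanced sampling across tribes,
allometry, correlated landmark noise along veins, missing landmarks, and
taxon-specific covariance structure. Passing tests therefore certify the
algorithmic pipeline under a known, favorable-but-noisy model, not
classifier performance on any real fauna.

## Problem sizes and tolerances

Test and acceptance runs use the default 640-specimen collection (and a
96-specimen reduced taxonomy for unit tests), 100 replicates for the
recovery experiment, and three generator seeds pooled for the hit-ratio
ordering check (the per-seed family error count is a small Poisson count
that can hit zero; pooling makes the ordering a property of the conditions
rather than of one draw). Numerical tolerances: GPA tol 1e-8 (tests use
1e-12 where asserting 1e-8 equalities), whitening verified to 1e-6,
posterior normalization to 1e-9, OPA verified against a 1e-3-step rotation
grid to 1e-5.
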