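# Methods

## Model and assumptions

The unit of analysis is a balanced two-factor community survey: factors A
(r levels) and B (m levels) crossed so that exactly one community is
observed per (i, j) cell, giving rm proportion vectors
**p**<sub>ij</sub> over a common pool of S species, plus an S × S species
dissimilarity matrix **Δ**. The method assumes:

* **Δ is Euclidean** — the species can be placed in a Euclidean space with
  pairwise distances δ<sub>kl</sub>. Square-root patristic distances on a
  tree and the rank-based taxonomic distances are Euclidean by
  construction; arbitrary user matrices are verified with the Gower
  eigenvalue check and refused if they fail (no Lingoes/Cailliez
  correction is applied: silently altering the metric would change the
  diversity being partitioned).
* **Balanced crossing with even weights** — communities weigh 1/(rm), A
  levels 1/r, B levels 1/m. A user-supplied community weight vector is
  accepted and propagated consistently to level weights and aggregated
  proportions (so the centroid identities continue to hold), but the
  semantics of unbalanced or replicated designs are out of scope.
* Proportions are compositional: each column sums to 1. Species absent
  from every community are dropped (their ordination weight would be zero
  and the weighted metric degenerate) with a warning.

All entropy computations use **D** = **Δ**²⁄2. In that scale Rao's
quadratic entropy of the global proportion vector equals the inertia of
the species cloud, DISC equals half squared centroid distance, and the
six ANOQE components (SST, SSW, SSC, SSA, SSB, SSAB) equal the inertias
of the corresponding clouds. `quadratic_entropy`/`cross_entropy` also
accept a raw **D** for general use; only the decomposition fixes the
scale.

The SSA component is computed as QE(**p**<sub>++</sub>) − Σ<sub>i</sub>
a<sub>i</sub> QE(**p**<sub>i+</sub>), which is algebraically the A-level
centroid inertia Σ<sub>i</sub> a<sub>i</sub>‖A<sub>i</sub>‖²; the test
suite checks the two routes against each other on 100 random datasets.
SSAB is defined as SSC − SSA − SSB, making the decomposition exact by
construction; it is independently verified to equal the inertia of the
re-centred interaction points Σ<sub>ij</sub>.

## Numerical choices

* **Weighted PCoA.** The Gower matrix
  (I − **1w**ᵗ)(−Δ²/2)(I − **w1**ᵗ) is symmetrised through
  diag(w)<sup>1/2</sup> and decomposed with `scipy.linalg.eigh`.
  Axes with λ ≤ 1e−9·λ_max are discarded; an eigenvalue below
  −1e−9·λ_max aborts with a message naming the Euclidean check. The same
  relative tolerance governs the rank of the B-level cloud in version 2
  (and thereby its dim(G_X) > dim(G_B) precondition).
* **Sign convention.** Each axis is flipped so its largest-magnitude
  species coordinate is positive; principal axes of level clouds inherit
  the convention through the projected species scores. Scores are
  otherwise sign-arbitrary, and with tied eigenvalues the subspace is
  rotation-arbitrary — tests compare only rotation-invariant quantities
  there.
* **Clamping.** Components that come out negative by less than 1e−12
  through floating-point cancellation are clamped to zero (logged at
  debug level); anything more negative is left to trip the invariant
  checks.
* **Percent of variance** is reported both relative to the retained-axis
  sum and relative to the exact SS reference of the analysed factor. The
  two coincide exactly for version 1 (no inertia is lost) but not for
  version 2, where the projection discards the collinear part.
* The version-2 projector is built from an orthonormal basis of the
  co-factor cloud's principal axes (not the raw level points), so it is
  idempotent and basis-invariant regardless of m or degenerate
  eigenvalues.

## The synthetic generator

`simulate_table` emulates the shape of a crossed field survey: defaults
are S = 30 species on a random pure-birth phylogeny, r = 5 × m = 6
communities (the shape of a five-location, six-stage succession survey),
unit log-scale effects for both factors, no interaction, and exact
proportions. Effects are clade shifts: each level of a factor adds its
effect magnitude to the log-abundance of one clade's species, then a
softmax produces strictly positive proportions; finite `n_individuals`
adds multinomial sampling noise on top. Clade assignment can be
`disjoint` (factors perturb disjoint species sets, so their effect
directions are orthogonal), `overlapping`, or `collinear` (A shifts the
same clades as B — the regime version 2 is designed to expose). Singleton
leaves count as degenerate clades so that disjoint assignment stays
feasible on small trees; the interaction term draws a per-cell clade and
a random ±1 sign so it is non-additive even when few disjoint clades
remain. Sub-seeds for tree, abundances, and sampling are derived from the
single seed by fixed offsets, so each stage is independently
reproducible.

What the generator does **not** emulate: real surveys have unbalanced
richness, zero-inflation, spatial autocorrelation among communities, and
phylogenies with calibrated depths. Passing tests therefore demonstrate
the algebraic and statistical correctness of the method on its stated
model — exact partition and duality identities, correct behaviour of the
two projection schemes, monotone recovery of effect size — not
robustness to field-data pathologies.

## Problem sizes in tests and the acceptance script

The randomised suites use 100 datasets with S ≤ 30 and r, m ≤ 5
(identities are exact at any size, so small instances carry the same
evidence), a 5-point effect grid × 20 seeds at S = 20 for the
dose–response check, and one 30-species 5 × 6 reference study in
`scripts/acceptance.py`. Everything runs in well under a minute on one
CPU.

## Known limitations

* Only balanced designs with one community per cell; replicated plots or
  missing cells require aggregation upstream.
* Non-Euclidean dissimilarities are refused rather than corrected.
* Nodal (edge-count) tree distances are *not* guaranteed Euclidean in
  general; the pipeline checks and errors rather than transforming them
  silently. A degree-2 root is treated as a real node (both incident
  edges counted) unless `collapse_root=True`.
* No significance testing: the partition is descriptive, and permutation
  schemes for crossed designs raise exchangeability questions the package
  does not take a position on.
* The published five-location bird survey that motivates the default
  simulation shape is not redistributable here; analyses of it require a
  locally provided copy of the densities table and composite supertree.
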