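# xdpcoa — crossed-factor double principal coordinate analysis

`xdpcoa` partitions and visualises the diversity of ecological communities
classified by **two crossed factors** — e.g. bird assemblages surveyed in
*r* locations × *m* successional habitat stages — taking into account how
different the species are from one another (phylogenetically,
taxonomically, or functionally). It is aimed at community ecologists and
biodiversity statisticians who want more than a scalar diversity index:
which levels of a factor drive the differences, which species or clades
carry them, and what remains of one factor once the other is controlled
for.

## The model

The data are a species × community table of nonnegative importance values
(densities, abundances, biomass, or presence/absence), one community per
cell of a balanced *r* × *m* design, and a **Euclidean** dissimilarity
matrix **Δ** = (δ<sub>kl</sub>) among the *S* species (square-root
patristic distances, taxonomic rank distances, trait distances …).
Columns are normalised to proportion vectors **p**<sub>ij</sub>.

Diversity is measured by Rao's quadratic entropy with
**D** = **Δ**²⁄2:

> QE(**p**) = **p**ᵗ**D p**,  DISC(**p**₁, **p**₂) = **p**₁ᵗ**D p**₂ − ½(**p**₁ᵗ**D p**₁ + **p**₂ᵗ**D p**₂)

A principal coordinate analysis of **Δ** weighted by the global species
proportions embeds the species as points M<sub>k</sub> with
‖M<sub>k</sub> − M<sub>l</sub>‖ = δ<sub>kl</sub>; communities and factor
levels sit at the weighted centroids of their species, and
½‖C<sub>ij</sub> − C<sub>i'j'</sub>‖² = DISC(**p**<sub>ij</sub>,
**p**<sub>i'j'</sub>) — the "double" embedding. Cloud inertias then
reproduce the ANOVA-like partition of quadratic entropy (ANOQE):

> SST = SSW + SS(C),  SS(C) = SS(A) + SS(B) + SS(A,B)

computed both ways (entropy formulas and cloud inertias) and agreeing to
1e−8 in the test suite.

Two conditional ordinations display factor A given factor B:

* **version 1 (mean-based)** recentres communities by their B-level
  centroid and takes the principal axes of the A-level cloud (eigenvalue
  sum = SS(A));
* **version 2 (structure-based)** additionally projects every point onto
  the orthogonal complement of the subspace spanned by B's level cloud,
  discarding any A signal collinear with B's structure (eigenvalue sum
  ≤ SS(A)). Use it when A and B are suspected to be associated.

## Worked example

Simulate a 12-species survey over a 2 × 3 design with clade-structured
effects of both factors, then partition its diversity:

```sh
xdpcoa simulate --species 12 --levels-a 2 --levels-b 3 \
    --effect-a 1.0 --effect-b 0.8 --seed 3 --out demo
xdpcoa partition --table demo/table.tsv --design demo/design.tsv \
    --tree demo/tree.nwk --sqrt-branch --out demo/part
```

```json
{
  "SST": 2.599202976052706,
  "SSW": 2.509849231818508,
  "SSC": 0.08935374423419784,
  "SSA": 0.049810868424871035,
  "SSB": 0.0391867235398764,
  "SSAB": 0.0003561522694504049,
  ...
}
```

Most diversity (SSW, 96.6 % of SST) is inside communities — typical for
proportion data — and the among-community share splits into a factor-A
effect (SSA), a factor-B effect (SSB), and a negligible interaction
(SSAB). The two conditional ordinations of factor A given B:

```sh
xdpcoa crossed --table demo/table.tsv --design demo/design.tsv \
    --tree demo/tree.nwk --sqrt-branch --version 1 --factor A --out demo/v1
# v1: 1 retained axes
#        eigenvalue  percent_of_retained  percent_of_ss
# axis1      0.0498             100.0000       100.0000
xdpcoa crossed ... --version 2 --factor A --out demo/v2
# v2: 1 retained axes
#        eigenvalue  percent_of_retained  percent_of_ss
# axis1      0.0497             100.0000        99.8407
```

Version 1 recovers all of SS(A) = 0.0498 on one axis; version 2 keeps
99.8 % of it, so here factor A acts almost orthogonally to factor B (the
simulation shifted disjoint clades). Each output directory holds
`eigenvalues.tsv`, the species/community/level coordinate tables, and an
`inertia_report.json` with the exact SS references.

The same pipeline is available as a library
(`weighted_pcoa`, `place_points`, `anoqe`, `crossed_dpcoa_v1/2`, …), and
`xdpcoa dpcoa --factor B` gives the preliminary main-effect ordination.

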