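"""Species dissimilarity matrices from trees, taxonomies, or files.

The ordination machinery requires a Euclidean dissimilarity matrix
``Delta``: the species must be embeddable as points of a Euclidean space
whose pairwise distances equal ``delta_kl``.  This module builds such
matrices from phylogenies (nodal or square-root patristic distances),
from taxonomies (Clarke-style rank distances), or as equidistant
configurations, and provides the Gower eigenvalue check for Euclidean
embeddability.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "DissimilarityMatrix",
    "nodal_distance",
    "sqrt_branch_distance",
    "taxonomic_distance",
    "equidistance",
    "is_euclidean",
    "read_distance_matrix",
    "write_distance_matrix",
]

DEFAULT_EUCLIDEAN_TOL = 1e-10


@dataclass
class DissimilarityMatrix:
    """A labelled symmetric matrix of species dissimilarities ``delta_kl``.

    Parameters
    ----------
    labels
        Ordered species identifiers (length S).
    values
        S x S array of nonnegative dissimilarities with zero diagonal.
    euclidean_checked
        Tri-state embeddability status: ``None`` (unknown), ``True``, or
        ``False``; set by :func:`is_euclidean`.
    """

    labels: list[str]
    values: np.ndarray
    euclidean_checked: Optional[bool] = field(default=None)

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        s = len(self.labels)
        if len(set(self.labels)) != s:
            raise ValueError("duplicate species labels in dissimilarity matrix")
        if self.values.shape != (s, s):
            raise ValueError(
                f"dissimilarity matrix shape {self.values.shape} does not match "
                f"{s} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("dissimilarity matrix diagonal is not zero")
        if np.any(self.values < 0):
            raise ValueError("dissimilarity matrix has negative entries")
        # canonicalise: exact symmetry and zero diagonal
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_species(self) -> int:
        return len(self.labels)

    def reorder(self, labels: Sequence[str]) -> "DissimilarityMatrix":
        """Return a copy restricted to / reordered by ``labels``."""
        idx = [self.labels.index(str(l)) for l in labels]
        return DissimilarityMatrix(
            [self.labels[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            euclidean_checked=self.euclidean_checked,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _leaf_taxa(tree: dendropy.Tree) -> list:
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    if any(t is None or t.label is None for t in taxa):
        raise ValueError("all leaves must carry a label")
    labels = [t.label for t in taxa]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    if len(labels) < 2:
        raise ValueError("tree must have at least two leaves")
    order = np.argsort(labels)
    return [taxa[i] for i in order]


def nodal_distance(
    tree: dendropy.Tree | str, collapse_root: bool = False
) -> DissimilarityMatrix:
    """Number of edges on the path connecting each pair of leaves.

    A degree-2 root produced by reading a rooted Newick string is kept as a
    real node, so the two edges it subtends are both counted; pass
    ``collapse_root=True`` to merge them into one edge first.
    """
    tree = _as_tree(tree)
    if collapse_root:
        tree = tree.clone(depth=1)
        tree.collapse_basal_bifurcation()
    taxa = _leaf_taxa(tree)
    pdm = tree.phylogenetic_distance_matrix()
    s = len(taxa)
    d = np.zeros((s, s))
    for k in range(s):
        for l in range(k + 1, s):
            d[k, l] = d[l, k] = pdm.path_edge_count(taxa[k], taxa[l])
    return DissimilarityMatrix([t.label for t in taxa], d)


def sqrt_branch_distance(tree: dendropy.Tree | str) -> DissimilarityMatrix:
    """Square root of the patristic (branch-length sum) distance.

    The square-root transform makes tree distances Euclidean-embeddable,
    so the result always passes :func:`is_euclidean`.
    """
    tree = _as_tree(tree)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            raise ValueError("tree has edges with missing branch lengths")
        if edge.length < 0:
            raise ValueError("tree has negative branch lengths")
    taxa = _leaf_taxa(tree)
    pdm = tree.phylogenetic_distance_matrix()
    s = len(taxa)
    d = np.zeros((s, s))
    for k in range(s):
        for l in range(k + 1, s):
            d[k, l] = d[l, k] = np.sqrt(pdm.patristic_distance(taxa[k], taxa[l]))
    return DissimilarityMatrix([t.label for t in taxa], d)


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    try:
        return dendropy.Tree.get(data=str(tree), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels in tree: {e}") from e


def taxonomic_distance(taxonomy: pd.DataFrame) -> DissimilarityMatrix:
    """Rank-based taxonomic dissimilarities.

    ``taxonomy`` has species as the index and one column per rank ordered
    from finest (e.g. genus) to coarsest (e.g. order).  Two species sharing
    their finest rank are at distance 1, sharing the next rank but not the
    finest at distance 2, and so on; two species sharing no listed rank are
    at distance L+1 where L is the number of ranks.  The result is an
    ultrametric and hence Euclidean after no further transform is needed
    for the rank values used here, but callers should still run
    :func:`is_euclidean` before ordination.
    """
    if taxonomy.isna().any().any():
        raise ValueError("taxonomy table has missing entries (ragged label paths)")
    labels = [str(x) for x in taxonomy.index]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species in taxonomy table")
    ranks = taxonomy.to_numpy(dtype=object)
    s, n_ranks = ranks.shape
    d = np.zeros((s, s))
    for k in range(s):
        for l in range(k + 1, s):
            shared = np.nonzero(ranks[k] == ranks[l])[0]
            d[k, l] = d[l, k] = (shared[0] + 1) if shared.size else n_ranks + 1
    return DissimilarityMatrix(labels, d)


def equidistance(species_labels: Sequence[str], c: float = np.sqrt(2)) -> DissimilarityMatrix:
    """All species at mutual dissimilarity ``c`` (a regular simplex).

    With ``c = sqrt(2)`` the induced squared-distance/2 matrix has unit
    off-diagonal entries, the configuration under which the ordination
    reduces to non-symmetrical correspondence analysis.
    """
    if not c > 0:
        raise ValueError("equidistance constant c must be positive")
    s = len(species_labels)
    d = np.full((s, s), float(c))
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(list(species_labels), d)


def gower_centered(values: np.ndarray, weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Gower-centred cross-product matrix of a dissimilarity matrix.

    Returns ``(I - 1 w^t)(-Delta^2/2)(I - w 1^t)`` where ``w`` defaults to
    uniform weights.  Positive semi-definiteness of this matrix is
    equivalent to Euclidean embeddability of ``Delta``.
    """
    s = values.shape[0]
    w = np.full(s, 1.0 / s) if weights is None else np.asarray(weights, float)
    a = -0.5 * values**2
    centering = np.eye(s) - np.outer(np.ones(s), w)
    return centering @ a @ centering.T


def is_euclidean(D: DissimilarityMatrix, tol: float = DEFAULT_EUCLIDEAN_TOL) -> bool:
    """Check Euclidean embeddability by the Gower eigenvalue criterion.

    True iff the smallest eigenvalue of the double-centred ``-delta^2/2``
    matrix is no smaller than ``-tol`` times the largest one.  Updates
    ``D.euclidean_checked`` as a side effect.
    """
    g = gower_centered(D.values)
    eigvals = scipy.linalg.eigvalsh(0.5 * (g + g.T))
    lam_max = max(eigvals[-1], 0.0)
    ok = bool(eigvals[0] >= -tol * max(lam_max, 1e-300))
    D.euclidean_checked = ok
    return ok


# --- file round trips -------------------------------------------------------


def read_distance_matrix(path, fmt: str = "auto") -> DissimilarityMatrix:
    """Read a square labelled distance matrix (TSV/CSV or PHYLIP square)."""
    text = open(path).read() if not hasattr(path, "read") else path.read()
    if fmt == "auto":
        first = text.lstrip().splitlines()[0].split()
        fmt = "phylip" if len(first) == 1 and first[0].isdigit() else "tsv"
    if fmt == "phylip":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        s = int(lines[0].split()[0])
        labels, rows = [], []
        for ln in lines[1 : s + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return DissimilarityMatrix(labels, np.array(rows))
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python", index_col=0)
    if list(map(str, df.index)) != list(map(str, df.columns)):
        raise ValueError("distance matrix rows and columns must carry the same labels")
    return DissimilarityMatrix([str(x) for x in df.index], df.to_numpy(float))


def write_distance_matrix(D: DissimilarityMatrix, path, fmt: str = "tsv") -> None:
    if fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{D.n_species}\n")
            for lab, row in zip(D.labels, D.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")
    else:
        D.to_frame().to_csv(path, sep="\t")
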