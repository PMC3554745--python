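"""Rao quadratic entropy, cross-entropy, and the crossed ANOQE partition.

Quadratic entropy QE(p) = sum_kl p_k p_l d_kl is the expected
dissimilarity between two individuals drawn with replacement from the
proportion vector ``p``.  Rao's cross-entropy DISC measures the
dissimilarity between two proportion vectors.  Over a balanced crossed
design these combine into an ANOVA-like decomposition (ANOQE) of total
diversity into within-community, factor-A, factor-B, and interaction
components:

    SST = SSW + SS(C),   SS(C) = SS(A) + SS(B) + SS(A,B).

Everything here is computed directly from the entropy formulas with
``D = Delta^2 / 2`` — no eigendecomposition — so it serves as an exact
cross-check of the cloud inertias in the ordination space, where each
component equals the inertia of the corresponding point cloud.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .distances import DissimilarityMatrix
from .io_formats import FactorialCommunityTable, aggregate_proportions

__all__ = ["QEPartition", "quadratic_entropy", "cross_entropy", "anoqe"]

logger = logging.getLogger(__name__)

_CLAMP = 1e-12


@dataclass
class QEPartition:
    """The six ANOQE components, in squared-dissimilarity/2 units."""

    sst: float
    ssw: float
    ssc: float
    ssa: float
    ssb: float
    ssab: float

    def as_dict(self, percent: bool = True) -> dict:
        d = {
            "SST": self.sst,
            "SSW": self.ssw,
            "SSC": self.ssc,
            "SSA": self.ssa,
            "SSB": self.ssb,
            "SSAB": self.ssab,
        }
        if percent:
            tot = self.sst if self.sst > 0 else np.nan
            d["percent_of_SST"] = {k: 100.0 * v / tot for k, v in d.items()}
        return d


def _check_proportions(p: np.ndarray, d: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.shape[0] != d.shape[0]:
        raise ValueError(
            f"proportion vector length {p.shape} does not match D shape {d.shape}"
        )
    return p


def quadratic_entropy(p, D) -> float:
    """Rao's quadratic entropy ``p^t D p``.

    ``D`` is any symmetric zero-diagonal dissimilarity matrix; for the
    crossed decomposition it must be the half-squared species matrix
    ``Delta^2 / 2`` so that the DISC/inertia identities hold.
    """
    d = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    p = _check_proportions(p, d)
    return float(p @ d @ p)


def cross_entropy(p1, p2, D) -> float:
    """Rao's DISC dissimilarity between two proportion vectors.

    DISC(p1, p2) = p1^t D p2 - (p1^t D p1 + p2^t D p2) / 2.  With
    ``D = Delta^2 / 2`` and ``Delta`` Euclidean it is nonnegative and
    equals half the squared Euclidean distance between the two centroid
    points in the ordination space.
    """
    d = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    p1 = _check_proportions(p1, d)
    p2 = _check_proportions(p2, d)
    return float(p1 @ d @ p2 - 0.5 * (p1 @ d @ p1 + p2 @ d @ p2))


def _clamp(x: float, name: str) -> float:
    if x < 0:
        if x < -_CLAMP:
            return x  # genuinely negative: let the caller's invariants fail loudly
        logger.debug("clamping tiny negative %s = %g to 0", name, x)
        return 0.0
    return x


def anoqe(table: FactorialCommunityTable, Delta: DissimilarityMatrix) -> QEPartition:
    """Full crossed-design partition of quadratic entropy.

    All components are computed from QE/DISC with ``D = Delta^2/2`` under
    the table's stratum weights:

    * ``SST  = QE(p_global)`` — total diversity;
    * ``SSW  = sum_ij c_ij QE(p_ij)`` — mean within-community diversity;
    * ``SSC  = SST - SSW`` — among-community diversity;
    * ``SSA  = QE(p_global) - sum_i a_i QE(p_i+)`` — main effect of A
      (equivalently the level-A centroid inertia);
    * ``SSB`` analogous; ``SSAB = SSC - SSA - SSB`` — interaction.
    """
    Delta = Delta.reorder(table.species_labels)
    d_half_sq = 0.5 * Delta.values**2

    agg = aggregate_proportions(table)
    p_global = agg["p_global"].to_numpy()
    c = table.community_weights

    sst = quadratic_entropy(p_global, d_half_sq)
    ssw = sum(
        c[comm] * quadratic_entropy(table.proportions[comm].to_numpy(), d_half_sq)
        for comm in table.community_labels
    )
    ssc = _clamp(sst - ssw, "SSC")

    a_w = table.level_a_weights
    ssa = _clamp(
        sst
        - sum(
            a_w[lev] * quadratic_entropy(agg["P_A"][lev].to_numpy(), d_half_sq)
            for lev in table.levels_a
        ),
        "SSA",
    )
    b_w = table.level_b_weights
    ssb = _clamp(
        sst
        - sum(
            b_w[lev] * quadratic_entropy(agg["P_B"][lev].to_numpy(), d_half_sq)
            for lev in table.levels_b
        ),
        "SSB",
    )
    ssab = _clamp(ssc - ssa - ssb, "SSAB")
    return QEPartition(sst=sst, ssw=_clamp(ssw, "SSW"), ssc=ssc, ssa=ssa, ssb=ssb, ssab=ssab)
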