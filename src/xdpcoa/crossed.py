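"""Crossed-DPCoA: the conditional effect of one factor given the other.

Both versions start from the DPCoA space with species, communities, and
the two factors' level centroids placed in it.

*Main-effect analysis* finds the principal axes of one factor's level
cloud, equivalent to a DPCoA of the species x level proportion matrix.

*Version 1 (mean-based)* moves every level of the co-factor B to the
centre — communities are recentred as ``(Y_C)_ij - (Y_B)_j``, which
leaves the A-level centroids unchanged — then analyses the principal
axes of the A-level cloud.  The A-level inertia remains SS(A) and the
recentred community inertia is SS(A) + SS(A,B).

*Version 2 (structure-based)* also removes the whole subspace spanned by
B's level centroids: all points are projected onto the orthogonal
complement of the B cloud's principal axes before the A-level axes are
extracted.  Any component of A collinear with B's structure is lost, so
the retained A inertia can only shrink; use it when A is suspected to be
associated with B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dpcoa_space import OrdinationSpace, PointCloud, place_points, inertia
from .io_formats import FactorialCommunityTable, aggregate_proportions
from .qe_partition import anoqe
from .distances import DissimilarityMatrix

__all__ = ["CrossedResult", "main_effect_dpcoa", "crossed_dpcoa_v1", "crossed_dpcoa_v2"]

RANK_TOL = 1e-9


@dataclass
class CrossedResult:
    """Axes, eigenvalues, and projected scores of a crossed-DPCoA run.

    ``axis_percent_of_retained`` expresses each eigenvalue relative to
    the sum over retained axes; ``axis_percent_of_ss`` relative to the
    exact SS reference of the analysed factor (these coincide when the
    analysed cloud loses nothing to truncation or projection).
    """

    version: str
    axis_eigenvalues: np.ndarray
    axis_percent_of_retained: np.ndarray
    axis_percent_of_ss: np.ndarray
    species_scores: pd.DataFrame
    community_scores: pd.DataFrame
    level_a_scores: pd.DataFrame
    level_b_scores: pd.DataFrame
    inertia_report: dict = field(default_factory=dict)

    @property
    def n_axes(self) -> int:
        return len(self.axis_eigenvalues)

    def eigenvalue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.axis_eigenvalues,
                "percent_of_retained": self.axis_percent_of_retained,
                "percent_of_ss": self.axis_percent_of_ss,
            },
            index=[f"axis{i+1}" for i in range(self.n_axes)],
        )


def _principal_axes(coords: np.ndarray, weights: np.ndarray, tol: float = RANK_TOL):
    """Eigenpairs of the weighted covariance of a centred cloud.

    Returns descending positive eigenvalues and the matrix of orthonormal
    axis vectors (ambient-dim x q); q = 0 for a degenerate cloud.
    """
    cov = coords.T @ (coords * weights[:, None])
    eigvals, eigvecs = np.linalg.eigh(0.5 * (cov + cov.T))
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    lam_max = max(float(eigvals[0]) if eigvals.size else 0.0, 0.0)
    keep = eigvals > tol * lam_max if lam_max > 0 else np.zeros(eigvals.shape, bool)
    return eigvals[keep], eigvecs[:, keep]


def _clouds(space: OrdinationSpace, table: FactorialCommunityTable):
    agg = aggregate_proportions(table)
    y_c = place_points(
        space, table.proportions, table.community_weights.to_numpy(), "community"
    )
    y_a = place_points(space, agg["P_A"], table.level_a_weights.to_numpy(), "levelA")
    y_b = place_points(space, agg["P_B"], table.level_b_weights.to_numpy(), "levelB")
    return y_c, y_a, y_b


def _assemble(
    version: str,
    eigvals: np.ndarray,
    axes: np.ndarray,
    space: OrdinationSpace,
    species_coords: np.ndarray,
    community: PointCloud,
    level_a: PointCloud,
    level_b: PointCloud,
    ss_reference: float,
    report: dict,
) -> CrossedResult:
    def scores(coords):
        return coords @ axes

    sp = scores(species_coords)
    # sign convention: largest-magnitude species score positive on each axis
    if sp.size:
        idx = np.argmax(np.abs(sp), axis=0)
        signs = np.sign(sp[idx, np.arange(sp.shape[1])])
        signs[signs == 0] = 1.0
    else:
        signs = np.ones(axes.shape[1])
    axes = axes * signs

    cols = [f"axis{i+1}" for i in range(axes.shape[1])]

    def frame(coords, labels):
        return pd.DataFrame(scores(coords), index=labels, columns=cols)

    retained = eigvals.sum()
    return CrossedResult(
        version=version,
        axis_eigenvalues=eigvals,
        axis_percent_of_retained=100.0 * eigvals / retained if retained > 0 else eigvals * 0,
        axis_percent_of_ss=100.0 * eigvals / ss_reference if ss_reference > 0 else eigvals * 0,
        species_scores=frame(species_coords, space.labels),
        community_scores=frame(community.coords, community.labels),
        level_a_scores=frame(level_a.coords, level_a.labels),
        level_b_scores=frame(level_b.coords, level_b.labels),
        inertia_report=report,
    )


def _ss_lookup(table: FactorialCommunityTable, Delta: DissimilarityMatrix) -> dict:
    part = anoqe(table, Delta)
    return {
        "SST": part.sst,
        "SSW": part.ssw,
        "SSC": part.ssc,
        "SSA": part.ssa,
        "SSB": part.ssb,
        "SSAB": part.ssab,
    }


def main_effect_dpcoa(
    space: OrdinationSpace,
    table: FactorialCommunityTable,
    Delta: DissimilarityMatrix,
    factor: str = "B",
    tol: float = RANK_TOL,
) -> CrossedResult:
    """Principal axes of one factor's level cloud (preliminary analysis).

    Equivalent to a DPCoA applied to the species x level proportion
    matrix: the retained eigenvalues sum to SS(factor).  Species,
    communities, and both level clouds are projected onto the axes.
    """
    factor = factor.upper()
    if factor not in ("A", "B"):
        raise ValueError("factor must be 'A' or 'B'")
    levels = table.levels_a if factor == "A" else table.levels_b
    if len(levels) < 2:
        raise ValueError(f"factor {factor} has a single level; nothing to analyse")

    y_c, y_a, y_b = _clouds(space, table)
    target = y_a if factor == "A" else y_b
    eigvals, axes = _principal_axes(target.coords, target.weights, tol)
    ss = _ss_lookup(table, Delta)
    report = {
        "level_cloud_inertia": inertia(target),
        "community_cloud_inertia": inertia(y_c),
        "ss": ss,
    }
    return _assemble(
        f"main_effect_{factor}",
        eigvals,
        axes,
        space,
        space.coords,
        y_c,
        y_a,
        y_b,
        ss[f"SS{factor}"],
        report,
    )


def crossed_dpcoa_v1(
    space: OrdinationSpace,
    table: FactorialCommunityTable,
    Delta: DissimilarityMatrix,
    target_factor: str = "A",
    tol: float = RANK_TOL,
) -> CrossedResult:
    """Mean-based crossed-DPCoA of the target factor given the co-factor.

    Communities are recentred by subtracting their co-factor level
    centroid, the target level centroids are unchanged, and the axes are
    the principal axes of the target level cloud (eigenvalue sum equal to
    the target factor's SS component).
    """
    target_factor = target_factor.upper()
    if target_factor not in ("A", "B"):
        raise ValueError("target_factor must be 'A' or 'B'")
    y_c, y_a, y_b = _clouds(space, table)
    tgt, cof = (y_a, y_b) if target_factor == "A" else (y_b, y_a)
    cof_levels = (
        table.design["factor_b"] if target_factor == "A" else table.design["factor_a"]
    )
    cof_index = {lev: k for k, lev in enumerate(cof.labels)}
    recentred = y_c.coords - cof.coords[[cof_index[cof_levels[c]] for c in y_c.labels]]
    y_c_rec = PointCloud(y_c.labels, recentred, y_c.weights, "community")
    cof_rec = PointCloud(cof.labels, cof.coords * 0.0, cof.weights, cof.role)

    eigvals, axes = _principal_axes(tgt.coords, tgt.weights, tol)
    if axes.shape[1] == 0:
        warnings.warn(
            f"factor {target_factor} level cloud is degenerate (all levels at the "
            "same point); returning an empty result",
            stacklevel=2,
        )
    ss = _ss_lookup(table, Delta)
    f = target_factor
    other = "B" if f == "A" else "A"
    report = {
        "level_cloud_inertia": inertia(tgt),
        "community_cloud_inertia": inertia(y_c_rec, require_centred=False),
        "ss": ss,
        "expected_level_inertia": ss[f"SS{f}"],
        "expected_community_inertia": ss[f"SS{f}"] + ss["SSAB"],
    }
    lv_a, lv_b = (tgt, cof_rec) if f == "A" else (cof_rec, tgt)
    return _assemble(
        "v1", eigvals, axes, space, space.coords, y_c_rec, lv_a, lv_b, ss[f"SS{f}"], report
    )


def crossed_dpcoa_v2(
    space: OrdinationSpace,
    table: FactorialCommunityTable,
    Delta: DissimilarityMatrix,
    target_factor: str = "A",
    tol: float = RANK_TOL,
) -> CrossedResult:
    """Structure-based crossed-DPCoA: project out the co-factor subspace.

    An orthonormal basis of the co-factor level cloud's principal axes is
    removed from every point with the projector ``I - U U^t``; the axes
    are then the principal axes of the projected target level cloud.
    Requires the species space dimension to exceed the co-factor cloud's
    rank, otherwise the orthogonal complement is empty.
    """
    target_factor = target_factor.upper()
    if target_factor not in ("A", "B"):
        raise ValueError("target_factor must be 'A' or 'B'")
    y_c, y_a, y_b = _clouds(space, table)
    tgt, cof = (y_a, y_b) if target_factor == "A" else (y_b, y_a)

    _, u_cof = _principal_axes(cof.coords, cof.weights, tol)
    dim_gb = u_cof.shape[1]
    if space.n_axes <= dim_gb:
        raise ValueError(
            "orthogonal complement is empty: the species space has "
            f"{space.n_axes} principal axes but the co-factor level cloud spans "
            f"{dim_gb}; version 2 requires dim(G_X) > dim(G_B)"
        )

    def project(coords):
        return coords - (coords @ u_cof) @ u_cof.T

    species_p = project(space.coords)
    y_c_p = PointCloud(y_c.labels, project(y_c.coords), y_c.weights, "community")
    tgt_p = PointCloud(tgt.labels, project(tgt.coords), tgt.weights, tgt.role)
    cof_p = PointCloud(cof.labels, project(cof.coords), cof.weights, cof.role)

    eigvals, axes = _principal_axes(tgt_p.coords, tgt_p.weights, tol)
    ss = _ss_lookup(table, Delta)
    f = target_factor
    report = {
        "level_cloud_inertia": inertia(tgt_p),
        "community_cloud_inertia": inertia(y_c_p, require_centred=False),
        "ss": ss,
        "level_inertia_upper_bound": ss[f"SS{f}"],
        "community_inertia_upper_bound": ss[f"SS{f}"] + ss["SSAB"],
        "dim_complement_removed": dim_gb,
    }
    lv_a, lv_b = (tgt_p, cof_p) if f == "A" else (cof_p, tgt_p)
    return _assemble(
        "v2", eigvals, axes, space, species_p, y_c_p, lv_a, lv_b, ss[f"SS{f}"], report
    )
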