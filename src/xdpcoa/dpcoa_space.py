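"""The double principal coordinate (DPCoA) space.

A weighted principal coordinate analysis of the species dissimilarity
matrix ``Delta`` — each species weighted by its global proportion —
yields coordinates ``X`` whose rows ``M_k`` reproduce every pairwise
``delta_kl`` exactly.  Communities and factor levels are then placed at
the weighted centroids of their species, so that half the squared
distance between two placed points equals Rao's cross-entropy between
the corresponding proportion vectors: both the species dissimilarities
and the community dissimilarities live in one Euclidean space, hence
"double" PCoA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .distances import DissimilarityMatrix, gower_centered
from .io_formats import FactorialCommunityTable, aggregate_proportions

__all__ = [
    "OrdinationSpace",
    "PointCloud",
    "weighted_pcoa",
    "place_points",
    "inertia",
    "interaction_points",
]

AXIS_TOL = 1e-9


@dataclass
class OrdinationSpace:
    """Species coordinates on the principal axes of the weighted PCoA.

    ``coords`` is S x nu with rows ``M_k``; ``eigenvalues`` are the axis
    variances (descending, positive); ``weights`` are the species weights
    ``w_k`` (global proportions, summing to 1).  The axes are orthogonal
    in the diag(w) metric: ``X^t diag(w) X = diag(eigenvalues)`` and
    ``w^t X = 0``.
    """

    labels: list[str]
    coords: np.ndarray
    eigenvalues: np.ndarray
    weights: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    def species_cloud(self) -> "PointCloud":
        return PointCloud(self.labels, self.coords.copy(), self.weights.copy(), "species")

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords,
            index=self.labels,
            columns=[f"axis{i+1}" for i in range(self.n_axes)],
        )


@dataclass
class PointCloud:
    """A weighted set of points in the ordination space."""

    labels: list
    coords: np.ndarray
    weights: np.ndarray
    role: str = "points"

    def centroid(self) -> np.ndarray:
        return self.weights @ self.coords

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coords,
            index=self.labels,
            columns=[f"axis{i+1}" for i in range(self.coords.shape[1])],
        )


def weighted_pcoa(
    Delta: DissimilarityMatrix,
    weights,
    tol: float = AXIS_TOL,
) -> OrdinationSpace:
    """Principal coordinate analysis of ``Delta`` in the diag(w) metric.

    The Gower matrix ``G = (I - 1 w^t)(-Delta^2/2)(I - w 1^t)`` is
    eigendecomposed through the symmetric form
    ``diag(w)^{1/2} G diag(w)^{1/2}``; coordinates are
    ``X = diag(w)^{-1/2} V lambda^{1/2}``.  Axes with eigenvalues below
    ``tol * lambda_max`` are dropped; an eigenvalue more negative than
    that aborts, naming the Euclidean check, since it means ``Delta``
    cannot be embedded.

    Raises
    ------
    ValueError
        If any weight is nonpositive, weights do not sum to 1, or
        ``Delta`` is not Euclidean at the requested tolerance.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (Delta.n_species,):
        raise ValueError("species weights length does not match Delta")
    if np.any(w <= 0):
        raise ValueError(
            "species weights must be strictly positive "
            "(species with zero global proportion must be dropped first)"
        )
    if not np.isclose(w.sum(), 1.0, atol=1e-10):
        raise ValueError("species weights must sum to 1")

    g = gower_centered(Delta.values, w)
    sqw = np.sqrt(w)
    sym = sqw[:, None] * g * sqw[None, :]
    eigvals, eigvecs = scipy.linalg.eigh(0.5 * (sym + sym.T))
    order = np.argsort(eigvals, kind="stable")[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    lam_max = max(float(eigvals[0]), 0.0)
    if eigvals[-1] < -tol * max(lam_max, 1e-300):
        raise ValueError(
            "dissimilarity matrix is not Euclidean at this tolerance "
            f"(smallest eigenvalue {eigvals[-1]:.3g}); run is_euclidean() on the "
            "input and supply a Euclidean Delta"
        )
    keep = eigvals > tol * lam_max
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]

    coords = (eigvecs / sqw[:, None]) * np.sqrt(eigvals)[None, :]
    coords = _fix_signs(coords)
    Delta.euclidean_checked = True
    return OrdinationSpace(list(Delta.labels), coords, eigvals, w)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Flip each axis so its largest-magnitude coordinate is positive."""
    if coords.size == 0:
        return coords
    idx = np.argmax(np.abs(coords), axis=0)
    signs = np.sign(coords[idx, np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    return coords * signs


def place_points(
    space: OrdinationSpace,
    profiles: pd.DataFrame | np.ndarray,
    weights,
    role: str = "points",
    centred_contrast: bool = False,
) -> PointCloud:
    """Place profile columns at the weighted centroids of the species.

    Each column of ``profiles`` is a proportion vector over the space's
    species (or, with ``centred_contrast=True``, a zero-sum contrast such
    as the interaction residual); the point's coordinates are
    ``profile^t X``.  Clouds built from community or level profiles are
    centred at the origin because ``w^t X = 0`` and their weighted mean
    profile is the global proportion vector.
    """
    if isinstance(profiles, pd.DataFrame):
        if list(profiles.index) != list(space.labels):
            profiles = profiles.loc[space.labels]
        labels = list(profiles.columns)
        p = profiles.to_numpy(dtype=float)
    else:
        p = np.asarray(profiles, dtype=float)
        if p.ndim == 1:
            p = p[:, None]
        labels = list(range(p.shape[1]))
    if p.shape[0] != len(space.labels):
        raise ValueError("profile rows do not match the space's species")
    target = 0.0 if centred_contrast else 1.0
    if not np.allclose(p.sum(axis=0), target, atol=1e-8):
        raise ValueError(
            "profile columns must sum to 1 (or 0 for centred contrasts)"
        )
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (p.shape[1],):
        raise ValueError("one weight per profile column is required")
    return PointCloud(labels, p.T @ space.coords, weights, role)


def inertia(cloud: PointCloud, require_centred: bool = True, tol: float = 1e-8) -> float:
    """Weighted sum of squared distances of the points from the origin."""
    if require_centred:
        c = cloud.centroid()
        scale = max(np.abs(cloud.coords).max(initial=0.0), 1.0)
        if np.any(np.abs(c) > tol * scale):
            raise ValueError(
                f"cloud '{cloud.role}' is not centred (centroid {c}); "
                "pass require_centred=False to measure raw dispersion"
            )
    return float(cloud.weights @ np.einsum("ij,ij->i", cloud.coords, cloud.coords))


def interaction_points(space: OrdinationSpace, table: FactorialCommunityTable) -> PointCloud:
    """Interaction residual points ``Sigma_ij``.

    ``Sigma_ij`` sits at ``(p_ij - p_i+ - p_+j + p_global)^t X`` — where
    community ``ij`` would be if both factors' level centroids were moved
    to the centre.  The cloud's inertia is the interaction component
    SS(A,B) = SS(C) - SS(A) - SS(B).
    """
    agg = aggregate_proportions(table)
    contrasts = {}
    for comm in table.community_labels:
        i = table.design.loc[comm, "factor_a"]
        j = table.design.loc[comm, "factor_b"]
        contrasts[comm] = (
            table.proportions[comm]
            - agg["P_A"][i]
            - agg["P_B"][j]
            + agg["p_global"]
        )
    contrast_df = pd.DataFrame(contrasts)[table.community_labels]
    return place_points(
        space,
        contrast_df,
        table.community_weights.to_numpy(),
        role="interaction",
        centred_contrast=True,
    )
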