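"""Community tables over a balanced two-factor design.

Reads species x community importance tables (densities, abundances,
biomass, cover ...) plus a design table assigning each community to one
level of factor A and one level of factor B, validates the balanced
crossing, and normalises importance values to within-community
proportions ``p_ijk``.  Also houses the presence/absence rule, simple
variance-taming transforms, the stratum-wise aggregation of proportions,
and writers for all result tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FactorialCommunityTable",
    "read_community_table",
    "presence_absence",
    "transform_values",
    "aggregate_proportions",
    "write_results",
]

PROPORTION_TOL = 1e-12


@dataclass
class FactorialCommunityTable:
    """Species proportions over a complete balanced r x m crossed design.

    ``raw`` and ``proportions`` are species x community DataFrames sharing
    the same labels; ``design`` maps each community label to its
    ``(factor_a, factor_b)`` levels.  Weights default to even at every
    stratum: 1/(rm) per community, 1/r per A level, 1/m per B level.
    """

    raw: pd.DataFrame
    design: pd.DataFrame  # index: community; columns: factor_a, factor_b
    community_weights: Optional[pd.Series] = None
    proportions: pd.DataFrame = field(init=False)
    levels_a: list = field(init=False)
    levels_b: list = field(init=False)

    def __post_init__(self) -> None:
        raw = self.raw.astype(float)
        if raw.isna().any().any():
            raise ValueError("community table contains missing values")
        if (raw.to_numpy() < 0).any():
            raise ValueError("community table contains negative values")
        if raw.index.duplicated().any():
            raise ValueError("duplicate species labels")
        if raw.columns.duplicated().any():
            raise ValueError("duplicate community labels")

        design = self.design
        missing = set(raw.columns) - set(design.index)
        extra = set(design.index) - set(raw.columns)
        if missing or extra:
            raise ValueError(
                f"design/table community mismatch: missing from design {sorted(missing)}, "
                f"missing from table {sorted(extra)}"
            )
        design = design.loc[raw.columns]
        self.levels_a = sorted(design["factor_a"].unique().tolist())
        self.levels_b = sorted(design["factor_b"].unique().tolist())
        cells = list(zip(design["factor_a"], design["factor_b"]))
        if len(set(cells)) != len(cells):
            raise ValueError("unbalanced design: duplicated (A, B) cell")
        if len(cells) != len(self.levels_a) * len(self.levels_b):
            raise ValueError(
                "unbalanced design: expected one community per (A, B) cell, got "
                f"{len(cells)} communities for {len(self.levels_a)} x {len(self.levels_b)} levels"
            )
        self.design = design

        col_sums = raw.sum(axis=0)
        if (col_sums <= 0).any():
            empty = col_sums.index[col_sums <= 0].tolist()
            raise ValueError(f"empty community (all-zero column): {empty}")

        zero_species = raw.index[raw.sum(axis=1) == 0]
        if len(zero_species):
            warnings.warn(
                f"dropping {len(zero_species)} species absent from every community: "
                f"{list(zero_species[:5])}{'...' if len(zero_species) > 5 else ''}",
                stacklevel=2,
            )
            raw = raw.drop(index=zero_species)
        self.raw = raw
        self.proportions = raw / raw.sum(axis=0)

        n = raw.shape[1]
        if self.community_weights is None:
            self.community_weights = pd.Series(1.0 / n, index=raw.columns)
        else:
            w = pd.Series(self.community_weights).astype(float)
            if set(w.index) != set(raw.columns):
                raise ValueError("community weights must be indexed by community label")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("community weights must be nonnegative and sum to 1")
            self.community_weights = w.loc[raw.columns]

    # -- derived structure ---------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.raw.shape[0]

    @property
    def r(self) -> int:
        return len(self.levels_a)

    @property
    def m(self) -> int:
        return len(self.levels_b)

    @property
    def species_labels(self) -> list:
        return list(self.raw.index)

    @property
    def community_labels(self) -> list:
        return list(self.raw.columns)

    def communities_of_a(self, level) -> list:
        return list(self.design.index[self.design["factor_a"] == level])

    def communities_of_b(self, level) -> list:
        return list(self.design.index[self.design["factor_b"] == level])

    @property
    def level_a_weights(self) -> pd.Series:
        w = self.community_weights
        return pd.Series(
            {a: w[self.communities_of_a(a)].sum() for a in self.levels_a}
        )

    @property
    def level_b_weights(self) -> pd.Series:
        w = self.community_weights
        return pd.Series(
            {b: w[self.communities_of_b(b)].sum() for b in self.levels_b}
        )

    def replace_raw(self, raw: pd.DataFrame) -> "FactorialCommunityTable":
        return FactorialCommunityTable(raw, self.design, self.community_weights)


def read_community_table(
    table_path, design_path, sep: Optional[str] = None,
    community_weights: Optional[pd.Series] = None,
) -> FactorialCommunityTable:
    """Read a species x community table and its crossed-design file.

    The separator is sniffed (tab or comma) unless ``sep`` is given.  The
    design file needs columns ``community``, ``factor_a``, ``factor_b``
    (any header names are accepted positionally).  Community labels, not
    column order, bind the two files together.
    """
    kwargs = dict(sep=sep) if sep else dict(sep=None, engine="python")
    table = pd.read_csv(table_path, index_col=0, **kwargs)
    design = pd.read_csv(design_path, index_col=0, **kwargs)
    if design.shape[1] < 2:
        raise ValueError("design file needs columns: community, factor A level, factor B level")
    design = design.iloc[:, :2]
    design.columns = ["factor_a", "factor_b"]
    table.index = table.index.map(str)
    table.columns = table.columns.map(str)
    design.index = design.index.map(str)
    return FactorialCommunityTable(table, design, community_weights)


def presence_absence(table: FactorialCommunityTable) -> FactorialCommunityTable:
    """Replace proportions by the presence/absence rule ``p_ijk = 1/S_ij``.

    Every species observed in a community gets equal proportion, where
    ``S_ij`` is that community's species richness.  Idempotent.
    """
    occ = (table.raw > 0).astype(float)
    return table.replace_raw(occ)


_TRANSFORMS = {
    "none": lambda x: x,
    "sqrt": np.sqrt,
    "log1p": np.log1p,
}


def transform_values(table: FactorialCommunityTable, transform: str) -> FactorialCommunityTable:
    """Apply a variance-taming transform to raw values, then renormalise.

    Square-root or log1p transforms damp the influence of hyperabundant
    species on the diversity decomposition.
    """
    try:
        fn = _TRANSFORMS[transform]
    except KeyError:
        raise ValueError(
            f"unknown transform {transform!r}; choose from {sorted(_TRANSFORMS)}"
        ) from None
    if transform == "none":
        return table
    return table.replace_raw(fn(table.raw))


def aggregate_proportions(table: FactorialCommunityTable) -> dict:
    """Stratum-wise species proportion vectors.

    Returns ``P_A`` (species x r, column i is ``p_{i+}``), ``P_B``
    (species x m, ``p_{+j}``) and ``p_global`` (``p_{++}``), each a
    community-weight-weighted mean of the member communities' proportion
    vectors — with even weights, the plain arithmetic mean.
    """
    p = table.proportions
    w = table.community_weights

    def _stratum(levels, members) -> pd.DataFrame:
        cols = {}
        for lev in levels:
            comms = members(lev)
            wl = w[comms]
            cols[lev] = (p[comms] * wl).sum(axis=1) / wl.sum()
        return pd.DataFrame(cols)

    P_A = _stratum(table.levels_a, table.communities_of_a)
    P_B = _stratum(table.levels_b, table.communities_of_b)
    p_global = (p * w).sum(axis=1) / w.sum()
    return {"P_A": P_A, "P_B": P_B, "p_global": p_global}


def write_results(
    out_dir,
    eigenvalues: Optional[pd.DataFrame] = None,
    species_coords: Optional[pd.DataFrame] = None,
    community_coords: Optional[pd.DataFrame] = None,
    level_a_coords: Optional[pd.DataFrame] = None,
    level_b_coords: Optional[pd.DataFrame] = None,
    partition: Optional[dict] = None,
) -> None:
    """Write result tables (TSV with headers) and partition.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "eigenvalues.tsv": eigenvalues,
        "species_coords.tsv": species_coords,
        "community_coords.tsv": community_coords,
        "levelA_coords.tsv": level_a_coords,
        "levelB_coords.tsv": level_b_coords,
    }
    for name, df in frames.items():
        if df is not None:
            df.to_csv(out / name, sep="\t")
    if partition is not None:
        (out / "partition.json").write_text(json.dumps(partition, indent=2) + "\n")
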