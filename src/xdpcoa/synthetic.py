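"""Synthetic balanced factorial community data on a random phylogeny.

Emulates the structure of a crossed field survey — a species pool with a
known phylogeny, sampled as one community per cell of a balanced r x m
design (e.g. locations x successional stages) — with controllable
factor-A, factor-B, and interaction effects.  Effects are clade shifts
on the log-abundance scale: each level of a factor multiplies the
abundance of one clade's species, so the signal is tree-structured, as
phylogenetically conserved habitat associations are in real communities.
A softmax maps log-abundances to strictly positive proportions
(``n_individuals=None``, the exact-proportion limit); finite
``n_individuals`` adds multinomial sampling noise.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io_formats import FactorialCommunityTable

__all__ = ["SimulationConfig", "random_tree", "simulate_table"]

# fixed offsets deriving independent sub-streams from the one user seed
_TREE_OFFSET = 101
_ABUNDANCE_OFFSET = 211
_SAMPLING_OFFSET = 307
_SEED_MOD = 2**31 - 1


@dataclass
class SimulationConfig:
    """Knobs of the factorial community simulation.

    ``effect_a``/``effect_b``/``effect_ab`` are log-scale shift
    magnitudes (0 = no effect; 1 means an e-fold abundance change of the
    affected clade).  ``clade_assignment`` controls how the affected
    clades relate: ``disjoint`` (each factor perturbs its own species,
    effects orthogonal), ``overlapping`` (clades drawn independently, may
    share species), ``collinear`` (factor A shifts the same clades as B,
    so A's signal lies inside B's subspace).
    """

    s: int = 30
    r: int = 5
    m: int = 6
    n_individuals: Optional[int] = None
    effect_a: float = 1.0
    effect_b: float = 1.0
    effect_ab: float = 0.0
    clade_assignment: str = "disjoint"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 2 or self.r < 2 or self.m < 2:
            raise ValueError("need s >= 2 species and at least 2 levels per factor")
        if min(self.effect_a, self.effect_b, self.effect_ab) < 0:
            raise ValueError("effect magnitudes must be nonnegative")
        if self.clade_assignment not in ("disjoint", "overlapping", "collinear"):
            raise ValueError("clade_assignment must be disjoint, overlapping or collinear")


def random_tree(s: int, seed: int = 0) -> dendropy.Tree:
    """Random binary phylogeny with ``s`` leaves labelled sp1..spS.

    A pure-birth topology with i.i.d. exponential branch lengths (plus a
    small floor so no two leaves coincide); deterministic per seed.
    """
    if s < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = _random.Random((seed + _TREE_OFFSET) % _SEED_MOD)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=s, rng=rng
    )
    np_rng = np.random.default_rng((seed + _TREE_OFFSET) % _SEED_MOD)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(np_rng.exponential(1.0) + 0.05)
    for k, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)):
        leaf.taxon.label = f"sp{k+1}"
    return tree


def _clades(tree: dendropy.Tree) -> list[frozenset]:
    """Leaf-label sets of the tree's nodes (singletons included), smallest first.

    Proper internal clades give phylogenetically clumped effects; leaf
    singletons are kept as degenerate clades so that disjoint assignment
    stays feasible on small trees.
    """
    out = []
    n_leaves = len(tree.leaf_nodes())
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 <= len(leaves) < n_leaves:
            out.append(leaves)
    return sorted(set(out), key=lambda c: (len(c), sorted(c)))


def _pick_disjoint(clades, counts, rng, slack: int = 0):
    """Pick groups of mutually disjoint clades, one group per factor.

    ``counts`` gives the group sizes; the last group may stop short at
    ``counts[-1] - slack`` members if the tree runs out of disjoint
    clades (used for the interaction pool, which only needs to be
    non-empty).
    """
    order = list(clades)
    rng.shuffle(order)
    all_leaves = set().union(*clades) if clades else set()
    minimums = list(counts)
    minimums[-1] = counts[-1] - slack
    if sum(minimums) > len(all_leaves):
        raise ValueError(
            "tree too small for disjoint clade assignment: "
            f"{sum(minimums)} disjoint clades requested but only "
            f"{len(all_leaves)} leaves available"
        )
    groups, used = [], set()
    still_needed = sum(minimums)
    for gi, count in enumerate(counts):
        group = []
        for clade in order:
            if len(group) == count:
                break
            if clade & used:
                continue
            # keep one unused leaf per pick still owed, so later groups
            # can always fall back to singletons
            owed_after = still_needed - (1 if len(group) < minimums[gi] else 0)
            if len(clade) > len(all_leaves) - len(used) - owed_after:
                continue
            if len(group) < minimums[gi]:
                still_needed -= 1
            group.append(clade)
            used |= clade
        if len(group) < minimums[gi]:
            raise ValueError(
                "tree too small for disjoint clade assignment: could not find "
                f"{minimums[gi]} further mutually disjoint clades"
            )
        groups.append(group)
    return groups


def simulate_table(config: SimulationConfig):
    """Simulate a balanced factorial community table with known truth.

    Returns ``(table, tree, truth)`` where ``truth`` records the clade
    of species shifted by each factor level.  Species proportions in
    community (i, j) are ``softmax(z + effect_a * 1[A-clade_i] +
    effect_b * 1[B-clade_j] + effect_ab * 1[AB-clade_ij])`` with baseline
    ``z ~ N(0, 1)`` shared across communities.
    """
    tree = random_tree(config.s, config.seed)
    labels = [f"sp{k+1}" for k in range(config.s)]
    rng = np.random.default_rng((config.seed + _ABUNDANCE_OFFSET) % _SEED_MOD)
    pyrng = _random.Random((config.seed + _ABUNDANCE_OFFSET) % _SEED_MOD)

    clades = _clades(tree)
    need_ab = config.effect_ab > 0
    n_cells = config.r * config.m
    if config.clade_assignment == "disjoint":
        counts = [config.r, config.m] + ([n_cells] if need_ab else [])
        groups = _pick_disjoint(clades, counts, pyrng, slack=n_cells - 1 if need_ab else 0)
        clades_a, clades_b = groups[0], groups[1]
        ab_pool = groups[2] if need_ab else []
    elif config.clade_assignment == "overlapping":
        clades_a = [pyrng.choice(clades) for _ in range(config.r)]
        clades_b = [pyrng.choice(clades) for _ in range(config.m)]
        ab_pool = [pyrng.choice(clades) for _ in range(n_cells)] if need_ab else []
    else:  # collinear: A shifts the same clades as B
        clades_b = [pyrng.choice(clades) for _ in range(config.m)]
        clades_a = [clades_b[i % config.m] for i in range(config.r)]
        ab_pool = [pyrng.choice(clades) for _ in range(n_cells)] if need_ab else []
    # per-cell clade (from the pool) and sign, so the interaction term is
    # non-additive even when the pool is small
    clades_ab = [pyrng.choice(ab_pool) for _ in range(n_cells)] if need_ab else []
    signs_ab = [pyrng.choice((-1.0, 1.0)) for _ in range(n_cells)] if need_ab else []

    baseline = rng.normal(0.0, 1.0, config.s)
    idx = {lab: k for k, lab in enumerate(labels)}

    def indicator(clade):
        v = np.zeros(config.s)
        v[[idx[l] for l in clade]] = 1.0
        return v

    columns, design_rows = {}, []
    truth = {
        "clades_a": {f"a{i+1}": sorted(c) for i, c in enumerate(clades_a)},
        "clades_b": {f"b{j+1}": sorted(c) for j, c in enumerate(clades_b)},
        "clades_ab": {},
    }
    for i in range(config.r):
        for j in range(config.m):
            z = baseline + config.effect_a * indicator(clades_a[i])
            z = z + config.effect_b * indicator(clades_b[j])
            if need_ab:
                cell = i * config.m + j
                clade_ij = clades_ab[cell]
                z = z + config.effect_ab * signs_ab[cell] * indicator(clade_ij)
                truth["clades_ab"][f"a{i+1}:b{j+1}"] = {
                    "clade": sorted(clade_ij),
                    "sign": signs_ab[cell],
                }
            p = np.exp(z - z.max())
            p /= p.sum()
            name = f"a{i+1}b{j+1}"
            columns[name] = p
            design_rows.append({"community": name, "factor_a": f"a{i+1}", "factor_b": f"b{j+1}"})

    raw = pd.DataFrame(columns, index=labels)
    if config.n_individuals is not None:
        srng = np.random.default_rng((config.seed + _SAMPLING_OFFSET) % _SEED_MOD)
        for name in raw.columns:
            raw[name] = srng.multinomial(config.n_individuals, raw[name].to_numpy()).astype(float)
        if (raw.sum(axis=0) <= 0).any():  # pragma: no cover - n_individuals >= 1 given
            raise ValueError("multinomial sampling produced an empty community")
    design = pd.DataFrame(design_rows).set_index("community")
    table = FactorialCommunityTable(raw, design)
    return table, tree, truth
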