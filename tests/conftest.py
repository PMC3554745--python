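"""Shared fixtures: hand-built 2x2 designs and a random simulated suite."""

import numpy as np
import pandas as pd
import pytest

import xdpcoa as x


DESIGN_2X2 = pd.DataFrame(
    {
        "factor_a": ["a1", "a1", "a2", "a2"],
        "factor_b": ["b1", "b2", "b1", "b2"],
    },
    index=["c11", "c12", "c21", "c22"],
)


def make_table(columns: dict, species=None) -> x.FactorialCommunityTable:
    """Balanced 2x2 table from raw column vectors keyed c11/c12/c21/c22."""
    species = species or [f"s{i+1}" for i in range(len(next(iter(columns.values()))))]
    raw = pd.DataFrame(columns, index=species)
    return x.FactorialCommunityTable(raw, DESIGN_2X2.loc[raw.columns])


@pytest.fixture
def pure_a_table():
    """Factor A fully determines composition; B and interaction are absent."""
    return make_table({"c11": [1, 0], "c12": [1, 0], "c21": [0, 1], "c22": [0, 1]})


@pytest.fixture
def pure_interaction_table():
    """Composition depends on the (A, B) cell jointly; both main effects vanish."""
    return make_table({"c11": [1, 0], "c12": [0, 1], "c21": [0, 1], "c22": [1, 0]})


@pytest.fixture
def delta_two():
    """Two equidistant species at delta = sqrt(2), so delta^2/2 = 1."""
    return x.equidistance(["s1", "s2"], np.sqrt(2))


def additive_2x2_table(u, v, alpha=0.1, beta=0.1, base=None):
    """2x2 proportions p_ij = p0 + (+/-alpha) u + (+/-beta) v.

    With equidistant species the DPCoA embedding is isometric to plain
    Euclidean geometry on the proportion vectors, so u and v are exactly
    the factor A and factor B displacement directions.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    s = len(u)
    p0 = np.full(s, 1.0 / s) if base is None else np.asarray(base, float)
    cols = {
        "c11": p0 + alpha * u + beta * v,
        "c12": p0 + alpha * u - beta * v,
        "c21": p0 - alpha * u + beta * v,
        "c22": p0 - alpha * u - beta * v,
    }
    assert all((c >= 0).all() for c in cols.values())
    return make_table(cols)


def build_analysis(table, delta):
    """Space, partition and the three placed clouds for a dataset."""
    delta = delta.reorder(table.species_labels)
    agg = x.aggregate_proportions(table)
    space = x.weighted_pcoa(delta, agg["p_global"].to_numpy())
    part = x.anoqe(table, delta)
    clouds = {
        "community": x.place_points(
            space, table.proportions, table.community_weights.to_numpy(), "community"
        ),
        "levelA": x.place_points(
            space, agg["P_A"], table.level_a_weights.to_numpy(), "levelA"
        ),
        "levelB": x.place_points(
            space, agg["P_B"], table.level_b_weights.to_numpy(), "levelB"
        ),
        "interaction": x.interaction_points(space, table),
    }
    return space, part, clouds


def random_dataset(seed: int):
    """One random balanced dataset (table, Delta) drawn from the simulator."""
    rng = np.random.default_rng(seed)
    r = int(rng.integers(2, 6))
    m = int(rng.integers(2, 6))
    cfg = x.SimulationConfig(
        s=int(rng.integers(r + m + 2, 31)),  # leaves enough clades for disjoint assignment
        r=r,
        m=m,
        n_individuals=int(rng.integers(200, 2000)) if rng.random() < 0.5 else None,
        effect_a=float(rng.uniform(0, 1.5)),
        effect_b=float(rng.uniform(0, 1.5)),
        effect_ab=float(rng.uniform(0, 1.0)) if rng.random() < 0.5 else 0.0,
        clade_assignment="overlapping" if rng.random() < 0.5 else "disjoint",
        seed=seed,
    )
    table, tree, _ = x.simulate_table(cfg)
    delta = x.sqrt_branch_distance(tree).reorder(table.species_labels)
    return table, delta


@pytest.fixture(scope="session")
def random_suite():
    """100 random simulated datasets with their spaces, partitions and clouds."""
    out = []
    for seed in range(100):
        table, delta = random_dataset(seed)
        space, part, clouds = build_analysis(table, delta)
        out.append({"table": table, "delta": delta, "space": space,
                    "partition": part, "clouds": clouds})
    return out
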