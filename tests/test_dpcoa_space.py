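"""The weighted PCoA space: exact distances, centroids, and inertias."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import xdpcoa as x
from conftest import build_analysis, make_table


class TestWeightedPcoa:
    def test_two_species_hand_solution(self):
        delta = x.DissimilarityMatrix(["s1", "s2"], np.array([[0, 2.0], [2.0, 0]]))
        space = x.weighted_pcoa(delta, [0.5, 0.5])
        assert space.n_axes == 1
        assert space.eigenvalues[0] == pytest.approx(1.0)
        assert sorted(space.coords[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_equilateral_three_species(self):
        delta = x.equidistance(["a", "b", "c"], 1.0)
        space = x.weighted_pcoa(delta, np.full(3, 1 / 3))
        assert space.n_axes == 2
        assert space.eigenvalues[0] == pytest.approx(space.eigenvalues[1])
        # total inertia = sum_{k!=l} w_k w_l delta^2/2 = 6 * (1/9) * (1/2)
        assert space.total_inertia == pytest.approx(1 / 3)

    def test_eigenvalue_sum_is_quadratic_entropy(self, random_suite):
        for case in random_suite[:20]:
            agg = x.aggregate_proportions(case["table"])
            qe = x.quadratic_entropy(
                agg["p_global"].to_numpy(), 0.5 * case["delta"].values ** 2
            )
            assert case["space"].total_inertia == pytest.approx(qe, abs=1e-8)

    def test_space_invariants_on_random_data(self, random_suite):
        for case in random_suite[:20]:
            space = case["space"]
            w = space.weights
            gram = space.coords.T @ (space.coords * w[:, None])
            assert np.allclose(gram, np.diag(space.eigenvalues), atol=1e-8)
            assert np.allclose(w @ space.coords, 0.0, atol=1e-10)
            dist = squareform(pdist(space.coords))
            assert np.allclose(dist, case["delta"].values, atol=1e-8)

    def test_non_euclidean_input_aborts(self):
        vals = np.array([[0, 1, 1], [1, 0, 2.5], [1, 2.5, 0]])
        delta = x.DissimilarityMatrix(["a", "b", "c"], vals)
        with pytest.raises(ValueError, match="[Ee]uclidean"):
            x.weighted_pcoa(delta, np.full(3, 1 / 3))

    def test_zero_weight_rejected(self):
        delta = x.equidistance(["a", "b", "c"], 1.0)
        with pytest.raises(ValueError, match="positive"):
            x.weighted_pcoa(delta, [0.5, 0.5, 0.0])

    def test_axis_sign_convention(self, random_suite):
        for case in random_suite[:10]:
            coords = case["space"].coords
            top = coords[np.argmax(np.abs(coords), axis=0), np.arange(coords.shape[1])]
            assert np.all(top > 0)


class TestPlacePoints:
    def test_concentrated_profile_lands_on_species(self, random_suite):
        case = random_suite[0]
        space = case["space"]
        profile = np.zeros(len(space.labels))
        profile[3] = 1.0
        cloud = x.place_points(space, profile, [1.0])
        assert np.allclose(cloud.coords[0], space.coords[3], atol=1e-12)

    def test_global_profile_lands_at_origin(self, random_suite):
        case = random_suite[0]
        agg = x.aggregate_proportions(case["table"])
        cloud = x.place_points(case["space"], agg["p_global"], [1.0])
        assert np.allclose(cloud.coords, 0.0, atol=1e-10)

    def test_level_is_centroid_of_its_communities(self, random_suite):
        for case in random_suite[:10]:
            t = case["table"]
            yc = case["clouds"]["community"]
            ya = case["clouds"]["levelA"]
            for k, lev in enumerate(t.levels_a):
                members = [t.community_labels.index(c) for c in t.communities_of_a(lev)]
                wm = t.community_weights.to_numpy()[members]
                centroid = (wm / wm.sum()) @ yc.coords[members]
                assert np.allclose(ya.coords[k], centroid, atol=1e-10)

    def test_clouds_are_centred(self, random_suite):
        for case in random_suite[:10]:
            for name in ("community", "levelA", "levelB", "interaction"):
                cloud = case["clouds"][name]
                assert np.allclose(cloud.centroid(), 0.0, atol=1e-10)

    def test_profile_sum_validated(self, random_suite):
        space = random_suite[0]["space"]
        bad = np.full(len(space.labels), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            x.place_points(space, bad, [1.0])


class TestInertia:
    def test_single_point_at_origin(self):
        cloud = x.PointCloud(["p"], np.zeros((1, 3)), np.ones(1))
        assert x.inertia(cloud) == 0.0

    def test_species_cloud_gives_sst(self, random_suite):
        for case in random_suite[:10]:
            assert x.inertia(case["space"].species_cloud()) == pytest.approx(
                case["partition"].sst, abs=1e-8
            )

    def test_community_cloud_gives_ssc(self, random_suite):
        for case in random_suite[:10]:
            assert x.inertia(case["clouds"]["community"]) == pytest.approx(
                case["partition"].ssc, abs=1e-8
            )

    def test_uncentred_cloud_flagged(self):
        cloud = x.PointCloud(["p", "q"], np.array([[1.0, 0], [1.0, 0]]), np.full(2, 0.5))
        with pytest.raises(ValueError, match="centred"):
            x.inertia(cloud)
        assert x.inertia(cloud, require_centred=False) == pytest.approx(1.0)


class TestInteractionPoints:
    def test_pure_a_collapses_to_origin(self, pure_a_table, delta_two):
        space, _, clouds = build_analysis(pure_a_table, delta_two)
        assert np.allclose(clouds["interaction"].coords, 0.0, atol=1e-12)

    def test_pure_interaction_inertia(self, pure_interaction_table, delta_two):
        space, part, clouds = build_analysis(pure_interaction_table, delta_two)
        assert x.inertia(clouds["interaction"]) == pytest.approx(0.5, abs=1e-10)
        assert x.inertia(clouds["interaction"]) == pytest.approx(part.ssc, abs=1e-10)

    def test_inertia_is_ssc_minus_main_effects(self, random_suite):
        for case in random_suite[:20]:
            part = case["partition"]
            got = x.inertia(case["clouds"]["interaction"])
            assert got == pytest.approx(part.ssc - part.ssa - part.ssb, abs=1e-8)


class TestNscaEquivalence:
    """With equidistant species, DPCoA reduces to non-symmetrical CA."""

    @staticmethod
    def _nsca(props: pd.DataFrame, weights: np.ndarray):
        """Direct NSCA of column profiles: weighted PCA of p_j - p_bar."""
        p = props.to_numpy()
        centred = p - (p * weights).sum(axis=1, keepdims=True)
        cov = (centred * weights) @ centred.T
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        keep = eigvals > 1e-10 * eigvals[0]
        return eigvals[keep], centred.T @ eigvecs[:, keep]

    @pytest.mark.parametrize("seed", range(8))
    def test_community_scores_match_direct_nsca(self, seed):
        rng = np.random.default_rng(seed)
        raw = pd.DataFrame(
            rng.uniform(0.1, 5.0, size=(3, 4)),
            index=["s1", "s2", "s3"],
            columns=["c11", "c12", "c21", "c22"],
        )
        t = make_table({c: raw[c].to_numpy() for c in raw.columns}, species=list(raw.index))
        delta = x.equidistance(t.species_labels, np.sqrt(2))
        space, _, clouds = build_analysis(t, delta)
        yc = clouds["community"]

        from xdpcoa.crossed import _principal_axes

        eigvals, axes = _principal_axes(yc.coords, yc.weights)
        scores = yc.coords @ axes

        nsca_eigvals, nsca_scores = self._nsca(
            t.proportions, t.community_weights.to_numpy()
        )
        assert np.allclose(eigvals, nsca_eigvals[: len(eigvals)], atol=1e-8)
        for k in range(scores.shape[1]):
            a, b = scores[:, k], nsca_scores[:, k]
            sign = np.sign(a[np.argmax(np.abs(a))] * b[np.argmax(np.abs(a))])
            assert np.allclose(a, sign * b, atol=1e-8)
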