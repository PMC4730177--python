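"""Fingerprint similarity / UPGMA / MDS, permutation group test,
Metastats-style differential abundance and the profile network rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from nifscape import cluster as cl
from nifscape import compare as cmp
from conftest import make_fragment


def table_from_counts(counts: pd.DataFrame, cutoff=0.08) -> cl.OtuTable:
    return cl.OtuTable(cutoff, counts, {}, {})


class TestPearson:
    def test_self_and_negation(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        sim = cmp.pearson_similarity_matrix({"a": v, "b": -v})
        assert sim.loc["a", "a"] == pytest.approx(1.0)
        assert sim.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        vs = {f"l{i}": rng.random(20) for i in range(3)}
        sim = cmp.pearson_similarity_matrix(vs)
        for a, b in itertools.combinations(vs, 2):
            x, y = vs[a] - vs[a].mean(), vs[b] - vs[b].mean()
            r = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
            assert sim.loc[a, b] == pytest.approx(r)

    def test_zero_variance_lane_named(self):
        with pytest.raises(ValueError, match="flat"):
            cmp.pearson_similarity_matrix({"ok": np.arange(4.0), "flat": np.ones(4)})


class TestUpgma:
    def test_two_lanes_single_merge(self):
        sim = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]], index=["a", "b"], columns=["a", "b"])
        tree = cmp.upgma(sim)
        assert sorted(tree.leaf_names()) == ["a", "b"]
        assert tree.children[0].length == pytest.approx(0.1)  # height = d/2

    def test_three_lane_hand_computation(self):
        d = {("A", "B"): 0.1, ("A", "C"): 0.4, ("B", "C"): 0.4}
        sim = pd.DataFrame(np.eye(3), index=list("ABC"), columns=list("ABC"))
        for (a, b), v in d.items():
            sim.loc[a, b] = sim.loc[b, a] = 1 - v
        tree = cmp.upgma(sim)
        inner = next(c for c in tree.children if not c.is_leaf)
        leaf_c = next(c for c in tree.children if c.is_leaf)
        assert sorted(inner.leaf_names()) == ["A", "B"]
        assert inner.children[0].length == pytest.approx(0.05)  # height of {A,B}
        assert leaf_c.length == pytest.approx(0.2)  # root height 0.4/2

    def test_matches_scipy_average_linkage(self):
        """Merge heights identical to scipy's UPGMA on random matrices."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            prof = pd.DataFrame(rng.random((6, 25)), index=list("ABCDEF"))
            sim = cmp.pearson_similarity_matrix(prof)
            tree = cmp.upgma(sim)
            d = 1 - sim.to_numpy()
            np.fill_diagonal(d, 0.0)
            z = hierarchy.linkage(squareform(d, checks=False), method="average")
            ours = []

            def heights(node, acc):
                if node.is_leaf:
                    return 0.0
                hs = [heights(c, acc) + (c.length or 0) for c in node.children]
                acc.append(hs[0])
                return hs[0]

            heights(tree, ours)
            assert np.allclose(sorted(np.asarray(ours) * 2), sorted(z[:, 2]))


class TestClassicalMds:
    def test_equilateral_triangle_reconstructed(self):
        d = pd.DataFrame(1 - np.eye(3), index=list("abc"), columns=list("abc"))
        coords = cmp.classical_mds(d, k=2)
        for a, b in itertools.combinations(range(3), 2):
            dist = np.linalg.norm(coords.iloc[a] - coords.iloc[b])
            assert dist == pytest.approx(1.0, abs=1e-9)

    def test_collinear_configuration_one_axis(self):
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        coords = cmp.classical_mds(pd.DataFrame(d, index=list("abc"), columns=list("abc")), k=2)
        assert np.allclose(coords["axis2"], 0.0, atol=1e-6)

    def test_duplicated_point_identical_coordinates(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        coords = cmp.classical_mds(pd.DataFrame(d, index=list("abc"), columns=list("abc")), k=1)
        assert np.allclose(coords.loc["a"], coords.loc["b"])

    def test_k_too_large_fails(self):
        with pytest.raises(ValueError):
            cmp.classical_mds(pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc")), k=3)


class TestPermutationGroupTest:
    def perfectly_separated(self):
        n = 8
        sim = np.full((n, n), 0.01)
        sim[:4, :4] = sim[4:, 4:] = 0.99
        np.fill_diagonal(sim, 1.0)
        ids = [f"s{i}" for i in range(n)]
        return pd.DataFrame(sim, index=ids, columns=ids), {
            f"s{i}": "g1" if i < 4 else "g2" for i in range(n)
        }

    def test_separated_blocks_reach_enumeration_floor(self):
        """p equals the exhaustive-permutation optimum (ties / all perms)."""
        sim, labels = self.perfectly_separated()
        n_perm = 9999
        stat, p = cmp.permutation_group_test(sim, labels, n_perm=n_perm, seed=0)
        assert stat > 0
        # exhaustive enumeration over all 8! label orders collapses to the
        # C(8,4)=70 group splits; only the 2 block-respecting splits tie
        # with the observed statistic
        assert p == pytest.approx((1 + 2 / 70 * n_perm) / (1 + n_perm), rel=0.25)
        assert p <= 0.05

    def test_deterministic_for_fixed_seed(self):
        sim, labels = self.perfectly_separated()
        p1 = cmp.permutation_group_test(sim, labels, n_perm=500, seed=3)
        p2 = cmp.permutation_group_test(sim, labels, n_perm=500, seed=3)
        assert p1 == p2

    def test_single_group_fails(self):
        sim, labels = self.perfectly_separated()
        with pytest.raises(ValueError):
            cmp.permutation_group_test(sim, {k: "g" for k in labels}, n_perm=10)


class TestMetastats:
    def labels(self, n=8):
        return {f"s{i}": "g1" if i < n // 2 else "g2" for i in range(n)}

    def test_identical_count_vectors_not_significant(self):
        block = np.tile([30, 10, 5, 55], (8, 1))
        counts = pd.DataFrame(block, index=[f"s{i}" for i in range(8)],
                              columns=[f"o{j}" for j in range(4)])
        res = cmp.metastats_test(counts, self.labels(), n_perm=500, seed=0)
        assert (res["p"] >= 0.9).all()

    def test_sparse_fisher_matches_exact_enumeration(self):
        counts = np.zeros((8, 2), dtype=int)
        counts[:, 1] = [1, 0, 0, 0, 1, 3, 3, 2]  # sparse OTU: 1 vs 9 pooled
        counts[:, 0] = 10 - counts[:, 1]  # depth 10 per... pooled 9 vs 1
        counts = pd.DataFrame(counts, index=[f"s{i}" for i in range(8)], columns=["dense", "sparse"])
        res = cmp.metastats_test(counts, self.labels(), n_perm=200, sparse_threshold=11, seed=0)
        # independent oracle: exhaustive hypergeometric enumeration
        probs = {k: hypergeom.pmf(k, 80, 10, 40) for k in range(11)}
        p_obs = probs[1]
        p_exact = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert res.loc["sparse", "method"] == "fisher"
        assert res.loc["sparse", "p"] == pytest.approx(p_exact, rel=1e-9)

    def test_worked_fisher_table_nine_vs_one(self):
        """Pooled 2x2 [[9,1],[1,9]] at depths 10/10: exact two-sided p."""
        counts = pd.DataFrame(
            {"focus": [3, 2, 2, 2, 1, 0, 0, 0], "rest": [0, 0, 0, 1, 2, 2, 3, 2]},
            index=[f"s{i}" for i in range(8)],
        )
        res = cmp.metastats_test(counts, self.labels(), n_perm=200, sparse_threshold=11, seed=0)
        probs = {k: hypergeom.pmf(k, 20, 10, 10) for k in range(11)}
        p_exact = sum(p for p in probs.values() if p <= probs[9] + 1e-12)
        assert p_exact == pytest.approx(0.00109333, rel=1e-4)
        assert res.loc["focus", "p"] == pytest.approx(p_exact, rel=1e-9)

    def test_requires_two_replicates_per_group(self):
        counts = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            cmp.metastats_test(counts, {"a": "g1", "b": "g1", "c": "g2"})


class TestProfileNetwork:
    def build(self, means_pct, reps=4, depth=1000):
        """Counts whose per-plant means (in % of depth) equal `means_pct`."""
        plants = [f"P{i}" for i in range(len(means_pct))]
        rows, idx, plant_of = [], [], {}
        for p, m in zip(plants, means_pct):
            for r in range(reps):
                focal = int(round(depth * m / 100))
                rows.append([focal, depth - focal])
                sid = f"{p}-{r}"
                idx.append(sid)
                plant_of[sid] = p
        counts = pd.DataFrame(rows, index=idx, columns=["otu_x", "otu_bg"])
        return table_from_counts(counts), plant_of

    @pytest.mark.parametrize(
        "means,expected",
        [
            ((3.0, 1.0, 0.5), ("P0",)),           # single-plant profile
            ((2.0, 1.8, 0.4), ("P0", "P1")),      # shared two-plant profile
            ((1.2, 1.1, 1.0), "excluded"),        # change below 1%
            ((4.0, 2.1, 1.9), "unassigned-altered"),  # no valid ratio split
        ],
    )
    def test_worked_assignment_rules(self, means, expected):
        table, plant_of = self.build(means)
        net = cmp.build_profile_network(table, plant_of)
        assert net.assignments["otu_x"] == expected

    def test_partition_invariant_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            counts = pd.DataFrame(
                rng.integers(0, 60, size=(12, 15)),
                index=[f"{p}-{r}" for p in "ABC" for r in range(4)],
                columns=[f"o{j}" for j in range(15)],
            )
            plant_of = {f"{p}-{r}": p for p in "ABC" for r in range(4)}
            net = cmp.build_profile_network(table_from_counts(counts), plant_of)
            assert set(net.assignments) | set(net.dropped) == set(counts.columns)

    def test_scale_invariance_to_depth(self):
        table1, plant_of = self.build((3.0, 1.0, 0.5), depth=500)
        table2, _ = self.build((3.0, 1.0, 0.5), depth=5000)
        n1 = cmp.build_profile_network(table1, plant_of)
        n2 = cmp.build_profile_network(table2, plant_of)
        assert n1.assignments == n2.assignments

    def test_edge_weights_are_mean_relative_abundances(self):
        table, plant_of = self.build((3.0, 1.0, 0.5))
        net = cmp.build_profile_network(table, plant_of)
        edges = cmp.network_edge_list(net)
        w = edges.loc[(edges.otu == "otu_x") & (edges.plant == "P0"), "weight"].iloc[0]
        assert w == pytest.approx(0.03)
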