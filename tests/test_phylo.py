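"""Neighbor joining, bootstrap support, outgroup rooting, newick IO and
canonical nifH cluster assignment."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from nifscape import phylo as ph
from nifscape import synthcomm as sc


def random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns
    (leaf ids, path-distance matrix, set of true bipartitions)."""
    ids = [f"t{i:02d}" for i in range(n_taxa)]
    subtrees = [ph.Node(name=i) for i in ids]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        for x in (a, b):
            x.length = float(rng.uniform(0.05, 1.0))
        parent = ph.Node(children=[a, b])
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [parent]
    for x in subtrees:
        x.length = float(rng.uniform(0.05, 1.0))
    root = ph.Node(children=subtrees)
    d = root.leaf_distances().loc[ids, ids].to_numpy()
    return ids, d, ph.bipartitions(root)


class TestProteinDistance:
    def test_poisson_correction_formula(self):
        peps = ["AAAA", "AAAC"]  # p = 0.25
        dm = ph.protein_distance(peps, ["a", "b"], correction="poisson")
        assert dm["a", "b"] == pytest.approx(-np.log(0.75))
        dm_p = ph.protein_distance(peps, ["a", "b"], correction="p")
        assert dm_p["a", "b"] == pytest.approx(0.25)

    def test_identical_pair_zero_under_both(self):
        for corr in ("p", "poisson"):
            dm = ph.protein_distance(["WXYZ"[0] * 5] * 2, ["a", "b"], corr)
            assert dm["a", "b"] == 0.0

    def test_saturated_distance_names_pair(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            ph.protein_distance(["AAAA", "CCCC"], ["a", "b"], "poisson")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = ph.neighbor_joining(DistanceMatrix(d, ["A", "B", "C"]))
        lengths = {lf.name: lf.length for lf in tree.leaves()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(0)
        ids, d, true_bp = random_additive_tree(rng, 4)
        tree = ph.neighbor_joining(DistanceMatrix(d, ids))
        assert np.allclose(tree.leaf_distances().loc[ids, ids].to_numpy(), d)
        assert ph.bipartitions(tree) == true_bp

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_consistency_random_trees(self, seed):
        """Topology and path distances recovered exactly from additive input."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 13))
        ids, d, true_bp = random_additive_tree(rng, n)
        tree = ph.neighbor_joining(DistanceMatrix(d, ids))
        assert ph.bipartitions(tree) == true_bp
        assert np.allclose(tree.leaf_distances().loc[ids, ids].to_numpy(), d, atol=1e-9)

    def test_topology_matches_skbio_oracle(self):
        rng = np.random.default_rng(42)
        ids, d, _ = random_additive_tree(rng, 8)
        ours = ph.bipartitions(ph.neighbor_joining(DistanceMatrix(d, ids)))
        ref_tree = skbio_nj(DistanceMatrix(d, ids))
        ref_bp = set()
        all_leaves = frozenset(ids)
        refleaf = min(ids)
        for node in ref_tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(ids) - 2:
                ref_bp.add(below if refleaf not in below else all_leaves - below)
        assert ours == ref_bp

    def test_too_few_taxa_fails(self):
        with pytest.raises(ValueError):
            ph.neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ["a", "b"]))


class TestBootstrapAndRooting:
    def test_forced_split_full_support(self):
        aln = {
            "a1": "AAAAAAAAAA" * 3,
            "a2": "AAAAAAAAAC" * 3,
            "a3": "AAAAAAAACA" * 3,
            "b1": "WWWWWWWWWW" * 3,
            "b2": "WWWWWWWWWC" * 3,
            "b3": "WWWWWWWWCW" * 3,
        }
        tree = ph.bootstrap_support(aln, n_reps=50, seed=1, correction="p")
        supports = [n.support for n in iter_internal(tree) if n.support is not None]
        assert max(supports) == pytest.approx(100.0)

    def test_identical_sequences_star_topology(self):
        aln = {f"x{i}": "AAAA" for i in range(4)}
        tree = ph.bootstrap_support(aln, n_reps=10, seed=0)
        assert sorted(tree.leaf_names()) == sorted(aln)

    def test_supports_deterministic_and_bounded(self):
        rng = np.random.default_rng(3)
        aln = {f"s{i}": "".join(rng.choice(list("ACDEFG"), size=40)) for i in range(6)}
        t1 = ph.bootstrap_support(aln, n_reps=30, seed=5)
        t2 = ph.bootstrap_support(aln, n_reps=30, seed=5)
        assert t1.to_newick() == t2.to_newick()
        for n in iter_internal(t1):
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0

    def test_rooting_three_leaf_bipartition(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        tree = ph.neighbor_joining(DistanceMatrix(d, ["A", "B", "C"]))
        rooted = ph.root_with_outgroup(tree, "C")
        assert len(rooted.children) == 2
        sides = [sorted(c.leaf_names()) for c in rooted.children]
        assert ["C"] in sides and ["A", "B"] in sides

    def test_rooting_preserves_leaf_distances_and_is_idempotent(self):
        rng = np.random.default_rng(8)
        ids, d, _ = random_additive_tree(rng, 7)
        tree = ph.neighbor_joining(DistanceMatrix(d, ids))
        r1 = ph.root_with_outgroup(tree, ids[0])
        assert np.allclose(r1.leaf_distances().loc[ids, ids].to_numpy(), d, atol=1e-9)
        r2 = ph.root_with_outgroup(r1, ids[0])
        assert ph.bipartitions(r2) == ph.bipartitions(r1)

    def test_missing_outgroup_fails(self, panel):
        tree = ph.neighbor_joining(
            ph.protein_distance([e.peptide for e in panel.entries[:4]], [e.taxon for e in panel.entries[:4]])
        )
        with pytest.raises(ValueError):
            ph.root_with_outgroup(tree, "nope")


class TestNewick:
    def test_round_trip_byte_stable(self):
        rng = np.random.default_rng(2)
        ids, d, _ = random_additive_tree(rng, 6)
        tree = ph.neighbor_joining(DistanceMatrix(d, ids))
        nw = tree.to_newick()
        assert ph.parse_newick(nw).to_newick() == nw
        rooted = ph.root_with_outgroup(tree, ids[3])
        nw2 = rooted.to_newick()
        assert ph.parse_newick(nw2).to_newick() == nw2


class TestClusterAssignment:
    def test_identical_to_reference_full_identity(self, panel):
        e = panel.ingroup[0]
        res = ph.assign_canonical_cluster({"otu1": e.peptide}, panel, {"otu1": 0.5})
        row = res.iloc[0]
        assert row.cluster == e.cluster and row.identity_pct == 100.0 and row.label_attached

    def test_subthreshold_identity_flagged(self, panel):
        e = panel.ingroup[0]
        pep = list(e.peptide)
        rng = np.random.default_rng(1)
        for i in rng.choice(len(pep), size=12, replace=False):  # ~89% identity
            pep[i] = "W" if pep[i] != "W" else "Y"
        res = ph.assign_canonical_cluster({"otu1": "".join(pep)}, panel)
        row = res.iloc[0]
        assert row.cluster in ("I", "III") and not row.label_attached
        assert row.identity_pct < 95.0

    def test_outgroup_never_donates_cluster(self, panel):
        res = ph.assign_canonical_cluster({"otu1": panel.outgroup.peptide}, panel)
        assert res.iloc[0].cluster == "unassigned"

    def test_low_abundance_not_designated(self, panel):
        e = panel.ingroup[0]
        res = ph.assign_canonical_cluster(
            {"otu1": e.peptide}, panel, {"otu1": 0.005}
        )
        assert not res.iloc[0].designated

    def test_cluster_monophyly_in_rooted_tree(self):
        """Simulated clusters I and III are monophyletic under the outgroup root."""
        hits = 0
        for seed in range(10):
            panel = sc.generate_reference_panel(8, 0.15, seed=seed)
            aln = {e.taxon: e.peptide for e in panel.entries}
            dm = ph.protein_distance(list(aln.values()), list(aln))
            rooted = ph.root_with_outgroup(ph.neighbor_joining(dm), panel.outgroup.taxon)
            clades = {frozenset(c.leaf_names()) for c in iter_clades(rooted)}
            want_I = frozenset(e.taxon for e in panel.ingroup if e.cluster == "I")
            want_III = frozenset(e.taxon for e in panel.ingroup if e.cluster == "III")
            if want_I in clades and want_III in clades:
                hits += 1
        assert hits >= 9


def iter_internal(node):
    if not node.is_leaf:
        yield node
        for c in node.children:
            yield from iter_internal(c)


def iter_clades(node):
    yield node
    for c in node.children:
        yield from iter_clades(c)
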