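"""Neighbor-joining phylogeny of OTU representatives.

Implements Saitou-Nei neighbor joining on protein distance matrices
(p-distance or Poisson-corrected), nonparametric bootstrap support by
column resampling with majority-rule bipartition frequencies mapped onto
the point-estimate tree, outgroup rooting on the pendant edge of a
BchL-like reference, and canonical nifH cluster assignment of OTU
representatives by nearest panel reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from Bio import Align

from .cluster import pairwise_distance
from .synthcomm import ReferencePanel


@dataclass
class Node:
    """Rooted tree node; `support` (%) annotates internal edges."""

    name: str = ""
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def _label(self) -> str:
        if self.is_leaf:
            lab = self.name
        else:
            lab = f"{self.support:g}" if self.support is not None else self.name
        return lab + (f":{self.length:.6g}" if self.length is not None else "")

    def to_newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self) -> str:
        if self.is_leaf:
            return self._label()
        inner = ",".join(c._newick_part() for c in self.children)
        return f"({inner})" + self._label()

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between all leaf pairs."""
        names = self.leaf_names()
        idx = {n: i for i, n in enumerate(names)}
        d = np.zeros((len(names), len(names)))

        def down(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            child_maps = []
            for c in node.children:
                m = {k: v + (c.length or 0.0) for k, v in down(c).items()}
                child_maps.append(m)
                acc.update(m)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for la, da in child_maps[a].items():
                        for lb, db in child_maps[b].items():
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
            return acc

        down(self)
        return pd.DataFrame(d, index=names, columns=names)


def parse_newick(text: str) -> Node:
    """Parse a Newick string (supports numeric internal labels)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character at {pos}: {s[pos]!r}")
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if s[pos] != ";":
        raise ValueError("trailing characters after newick tree")
    return root


def protein_distance(
    peptides: list[str], ids: list[str] | None = None, correction: str = "poisson"
) -> DistanceMatrix:
    """Protein distances on an equal-length alignment.

    correction="p" gives raw p-distance; "poisson" applies
    d = -ln(1 - p), the standard multiple-hit correction.
    """
    dm = pairwise_distance(peptides, ids)
    if correction == "p":
        return dm
    if correction != "poisson":
        raise ValueError("correction must be 'p' or 'poisson'")
    p = dm.data
    if (p >= 1.0).any():
        i, j = np.argwhere(p >= 1.0)[0]
        raise ValueError(
            f"saturated distance between {dm.ids[i]} and {dm.ids[j]}: p >= 1"
        )
    return DistanceMatrix(-np.log1p(-p), dm.ids)


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining; returns the tree on an unrooted
    (trifurcating-root) topology.

    Pair selection minimizes the Q criterion; ties are broken by the
    lexicographically smallest pair of subtree labels (each subtree
    labelled by its smallest leaf). Negative branch-length estimates are
    clamped to zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[Node] = [Node(name=i) for i in dm.ids]
    labels: list[str] = list(dm.ids)
    d = dm.data.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return max(float(x), 0.0)

    while len(active) > 3:
        m = len(active)
        act = np.array(active)
        sub = d[np.ix_(act, act)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        vals = q[iu]
        qmin = vals.min()
        ties = np.nonzero(np.isclose(vals, qmin, rtol=0, atol=1e-12))[0]
        best = None
        for t in ties:
            a, b = int(act[iu[0][t]]), int(act[iu[1][t]])
            key = tuple(sorted((labels[a], labels[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, i, j = best
        dij = d[i, j]
        ri = d[i, act].sum()
        rj = d[j, act].sum()
        li = 0.5 * dij + (ri - rj) / (2.0 * (m - 2))
        lj = dij - li
        parent = Node()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = clamp(li), clamp(lj)
        parent.children = [ci, cj] if labels[i] < labels[j] else [cj, ci]
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - dij)
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    a, b, c = sorted(active, key=lambda k: labels[k])
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = lk
    root = Node()
    root.children = [nodes[a], nodes[b], nodes[c]]
    return root


def bipartitions(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side not
    containing the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    parts: set[frozenset[str]] = set()

    def walk(node: Node, is_root: bool) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c, False) for c in node.children))
        if not is_root and 2 <= len(below) <= len(all_leaves) - 2:
            side = below if ref not in below else all_leaves - below
            parts.add(side)
        return below

    walk(tree, True)
    return parts


def bootstrap_support(
    alignment: dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
    correction: str = "poisson",
) -> Node:
    """NJ point tree with bootstrap support (%) on internal edges.

    Alignment columns are resampled with replacement `n_reps` times; the
    tree is rebuilt per replicate and each internal edge of the point
    tree receives the percentage of replicates containing its bipartition.
    Saturated replicate distances fall back to p-distance.
    """
    ids = sorted(alignment)
    seqs = [alignment[i] for i in ids]
    L = len(seqs[0])
    if L < 2:
        raise ValueError("alignment must have at least 2 columns")
    arr = np.array([list(s) for s in seqs])

    def tree_from(cols: np.ndarray) -> Node:
        peps = ["".join(row) for row in arr[:, cols]]
        try:
            dm = protein_distance(peps, ids, correction=correction)
        except ValueError:
            dm = protein_distance(peps, ids, correction="p")
        return neighbor_joining(dm)

    point = tree_from(np.arange(L))
    rng = np.random.default_rng(seed)
    tally: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        rep = tree_from(rng.integers(L, size=L))
        for bp in bipartitions(rep):
            tally[bp] = tally.get(bp, 0) + 1

    all_leaves = frozenset(ids)
    ref = min(all_leaves)

    def annotate(node: Node, is_root: bool) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, False) for c in node.children))
        if not is_root and 2 <= len(below) <= len(all_leaves) - 2:
            side = below if ref not in below else all_leaves - below
            node.support = 100.0 * tally.get(side, 0) / n_reps
        return below

    annotate(point, True)
    return point


def root_with_outgroup(tree: Node, outgroup: str) -> Node:
    """Root on the midpoint of the outgroup's pendant edge.

    Leaf-to-leaf path distances are preserved; rooting an already
    correctly rooted tree is a topological no-op.
    """
    if outgroup not in tree.leaf_names():
        raise ValueError(f"outgroup leaf {outgroup!r} not in tree")

    # collect undirected edges between frozen node objects
    edges: dict[int, list[tuple[Node, float]]] = {}
    objs: dict[int, Node] = {}

    def add_edge(a: Node, b: Node, ln: float) -> None:
        for x in (a, b):
            objs[id(x)] = x
        edges.setdefault(id(a), []).append((b, ln))
        edges.setdefault(id(b), []).append((a, ln))

    def collect(node: Node) -> None:
        for c in node.children:
            add_edge(node, c, c.length or 0.0)
            collect(c)

    collect(tree)
    # drop a redundant degree-2 old root by fusing its two edges
    if len(tree.children) == 2:
        a, b = tree.children
        la, lb = a.length or 0.0, b.length or 0.0
        edges[id(a)] = [(x, l) for x, l in edges[id(a)] if x is not tree] + [(b, la + lb)]
        edges[id(b)] = [(x, l) for x, l in edges[id(b)] if x is not tree] + [(a, la + lb)]
        del edges[id(tree)]

    out_leaf = next(lf for lf in tree.leaves() if lf.name == outgroup)
    (nbr, pend_len) = edges[id(out_leaf)][0]

    def build(node: Node, parent: Node | None, length: float, skip: Node | None = None) -> Node:
        fresh = Node(name=node.name if node.is_leaf else "", length=length, support=node.support)
        for child, ln in edges[id(node)]:
            if parent is not None and child is parent:
                continue
            if skip is not None and child is skip:
                continue
            fresh.children.append(build(child, node, ln))
        return fresh

    root = Node()
    og = Node(name=outgroup, length=pend_len / 2.0)
    rest = build(nbr, out_leaf, pend_len / 2.0)
    root.children = [og, rest]
    return root


# ---------------------------------------------------------------------------
# Canonical cluster assignment
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -1
    return a


def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity between two peptides."""
    if len(a) == len(b):
        same = sum(x == y for x, y in zip(a, b))
        return 100.0 * same / len(a)
    aln = _aligner().align(a, b)[0]
    matches = sum(
        1
        for sa, sb in zip(*aln.indices)
        if sa >= 0 and sb >= 0 and a[sa] == b[sb]
    )
    return 100.0 * matches / aln.length


def assign_canonical_cluster(
    representatives: dict[str, str],
    panel: ReferencePanel,
    relative_abundance: dict[str, float] | None = None,
    identity_threshold: float = 95.0,
    designation_threshold: float = 0.01,
) -> pd.DataFrame:
    """Assign each OTU representative to a canonical nifH cluster.

    The nearest panel reference (global-alignment % identity) donates its
    cluster label, except the outgroup, which never does ("unassigned").
    The reference's taxon label is attached only at >= identity_threshold
    % similarity; below that the OTU is flagged sub-threshold. OTUs under
    `designation_threshold` relative abundance are reported as not
    designated (the display rule for phylogram annotation), but keep
    their internal assignment.
    """
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    rows = []
    for otu in sorted(representatives):
        pep = representatives[otu]
        best_ref, best_id = None, -1.0
        for e in panel.entries:
            ident = percent_identity(pep, e.peptide)
            if ident > best_id:
                best_ref, best_id = e, ident
        cluster = "unassigned" if best_ref.cluster == "outgroup" else best_ref.cluster
        rel = None if relative_abundance is None else relative_abundance.get(otu, 0.0)
        rows.append(
            {
                "otu": otu,
                "cluster": cluster,
                "nearest_reference": best_ref.taxon,
                "identity_pct": best_id,
                "label_attached": bool(best_id >= identity_threshold),
                "designated": bool(rel is None or rel >= designation_threshold),
            }
        )
    return pd.DataFrame(rows)
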