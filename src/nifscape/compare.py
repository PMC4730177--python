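"""Community comparison.

Three arms, mirroring how fingerprint and amplicon data are compared in
functional-gene community studies:

* fingerprint arm — Pearson similarity between intensity profiles (or
  OTU abundance vectors), UPGMA dendrograms, classical (Torgerson) MDS
  ordination, and a permutation test on similarity matrices;
* differential-abundance arm — a Metastats-style per-OTU test combining
  a permutation (nonparametric) t-test for abundant OTUs with Fisher's
  exact test for sparse ones, FDR-controlled by Benjamini-Hochberg;
* network arm — the profile-clustering rule that assigns plant-specific
  OTUs to habitat profiles from mean relative-abundance changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import OtuTable
from .phylo import Node


def pearson_similarity_matrix(
    vectors: dict[str, np.ndarray] | pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation matrix between profiles (curve-based similarity)."""
    if isinstance(vectors, pd.DataFrame):
        ids = list(vectors.index)
        mat = vectors.to_numpy(dtype=float)
    else:
        ids = list(vectors)
        mat = np.array([np.asarray(vectors[i], dtype=float) for i in ids])
    if len(ids) < 2:
        raise ValueError("need at least two profiles")
    if not np.isfinite(mat).all():
        raise ValueError("profiles must be finite")
    sd = mat.std(axis=1)
    dead = [ids[i] for i in np.nonzero(sd == 0)[0]]
    if dead:
        raise ValueError(f"zero-variance profiles: {dead}")
    r = np.corrcoef(mat)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ids, columns=ids)


def upgma(similarity: pd.DataFrame) -> Node:
    """UPGMA dendrogram on distance = 1 - r; ultrametric heights = d/2.

    Ties in the merge queue are broken by the lexicographically smallest
    pair of cluster labels (smallest member id per cluster).
    """
    ids = list(similarity.index)
    n = len(ids)
    if n < 2:
        raise ValueError("UPGMA needs at least two profiles")
    d = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    nodes = [Node(name=i) for i in ids]
    sizes = [1] * n
    heights = [0.0] * n
    reps = list(ids)
    active = list(range(n))
    while len(active) > 1:
        act = np.array(active)
        sub = d[np.ix_(act, act)]
        iu = np.triu_indices(len(act), k=1)
        vals = sub[iu]
        dmin = vals.min()
        best = None
        for t in np.nonzero(vals == dmin)[0]:
            i, j = int(act[iu[0][t]]), int(act[iu[1][t]])
            key = tuple(sorted((reps[i], reps[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = dmin / 2.0
        parent = Node()
        for k in (i, j):
            nodes[k].length = h - heights[k]
        parent.children = sorted([nodes[i], nodes[j]], key=lambda nd: min(nd.leaf_names()))
        # arithmetic-mean update over member pairs
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (
                    sizes[i] + sizes[j]
                )
        nodes[i] = parent
        sizes[i] += sizes[j]
        heights[i] = h
        reps[i] = min(reps[i], reps[j])
        active.remove(j)
    return nodes[active[0]]


def classical_mds(distance: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix and embeds on the top-k
    eigenvectors; reproduces the input distances exactly when they are
    Euclidean-embeddable in k dimensions.
    """
    ids = list(distance.index)
    n = len(ids)
    if k >= n:
        raise ValueError("k must be smaller than the number of points")
    d = distance.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return pd.DataFrame(coords, index=ids, columns=[f"axis{a + 1}" for a in range(k)])


def permutation_group_test(
    similarity: pd.DataFrame,
    labels: dict[str, str],
    n_perm: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for group structure in a similarity matrix.

    Statistic: mean within-group similarity minus mean between-group
    similarity. The null is simulated by permuting sample labels; the
    p-value carries the +1 correction and therefore never returns 0.
    """
    ids = list(similarity.index)
    lab = np.array([labels[i] for i in ids])
    groups = sorted(set(lab))
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    if min((lab == g).sum() for g in groups) < 2:
        raise ValueError("need at least two samples per group")
    s = similarity.to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    vals = s[iu]
    same = lab[iu[0]] == lab[iu[1]]

    def statistic(same_mask: np.ndarray) -> float:
        return float(vals[same_mask].mean() - vals[~same_mask].mean())

    obs = statistic(same)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(ids))
        pl = lab[perm]
        if statistic(pl[iu[0]] == pl[iu[1]]) >= obs:
            count += 1
    return obs, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Metastats-style differential abundance
# ---------------------------------------------------------------------------


def metastats_test(
    counts: pd.DataFrame,
    labels: dict[str, str],
    n_perm: int = 1000,
    sparse_threshold: int = 8,
    seed: int = 0,
    pool_null: bool | None = None,
) -> pd.DataFrame:
    """Per-OTU two-group differential abundance on a count table.

    Abundant OTUs (pooled count >= sparse_threshold): two-sample t
    statistic on relative abundances with a label-permutation null
    (two-sided, +1 corrected). Sparse OTUs: two-sided Fisher's exact test
    on the pooled 2x2 count table. q-values by Benjamini-Hochberg across
    all OTUs.

    With few replicates per group the per-OTU permutation distribution is
    too discrete for useful p-values, so the null t statistics are pooled
    across OTUs (the small-sample convention of permutation-based
    differential-abundance testing), leaving the tested OTU out of its
    own null pool so that strong effects do not contaminate it;
    `pool_null=None` pools automatically when the smaller group has
    fewer than 8 replicates.
    """
    ids = list(counts.index)
    lab = np.array([labels[i] for i in ids])
    groups = sorted(set(lab))
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    ga, gb = (lab == groups[0]), (lab == groups[1])
    if ga.sum() < 2 or gb.sum() < 2:
        raise ValueError("need at least two replicates per group")
    x = counts.to_numpy(dtype=float)
    depth = x.sum(axis=1, keepdims=True)
    rel = x / np.maximum(depth, 1.0)

    def tstats(a_mask: np.ndarray, b_mask: np.ndarray) -> np.ndarray:
        ma, mb = rel[a_mask].mean(axis=0), rel[b_mask].mean(axis=0)
        va = rel[a_mask].var(axis=0, ddof=1) / a_mask.sum()
        vb = rel[b_mask].var(axis=0, ddof=1) / b_mask.sum()
        se = np.sqrt(va + vb)
        return np.where(se > 0, (ma - mb) / np.where(se > 0, se, 1.0), 0.0)

    t_obs = tstats(ga, gb)
    rng = np.random.default_rng(seed)
    n_a = int(ga.sum())
    if pool_null is None:
        pool_null = min(ga.sum(), gb.sum()) < 8
    null_t = np.empty((n_perm, x.shape[1]))
    for b in range(n_perm):
        perm = rng.permutation(len(ids))
        pa = np.zeros(len(ids), dtype=bool)
        pa[perm[:n_a]] = True
        null_t[b] = np.abs(tstats(pa, ~pa))
    if pool_null and x.shape[1] > 1:
        # leave-one-out pooled null: total exceedances minus own column's
        total = np.array([(null_t >= t) .sum() for t in np.abs(t_obs)])
        own = (null_t >= np.abs(t_obs)[None, :]).sum(axis=0)
        size = n_perm * (x.shape[1] - 1)
        p_perm = (1.0 + (total - own)) / (1.0 + size)
    else:
        exceed = (null_t >= np.abs(t_obs)[None, :]).sum(axis=0)
        p_perm = (1.0 + exceed) / (1.0 + n_perm)

    pooled = x.sum(axis=0)
    tot_a, tot_b = x[ga].sum(), x[gb].sum()
    p_out = np.empty(x.shape[1])
    method = np.empty(x.shape[1], dtype=object)
    for j in range(x.shape[1]):
        if pooled[j] < sparse_threshold:
            a_j, b_j = x[ga, j].sum(), x[gb, j].sum()
            table = [[a_j, tot_a - a_j], [b_j, tot_b - b_j]]
            p_out[j] = stats.fisher_exact(table, alternative="two-sided")[1]
            method[j] = "fisher"
        else:
            p_out[j] = p_perm[j]
            method[j] = "perm_t"
    q = multipletests(p_out, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "otu": counts.columns,
            "mean_rel_1": rel[ga].mean(axis=0),
            "mean_rel_2": rel[gb].mean(axis=0),
            "t": t_obs,
            "p": p_out,
            "q": q,
            "method": method,
        }
    ).set_index("otu")


# ---------------------------------------------------------------------------
# Profile clustering network
# ---------------------------------------------------------------------------


@dataclass
class ProfileNetwork:
    """Bipartite assignment of differential OTUs to plant profiles."""

    graph: nx.Graph
    assignments: dict[str, tuple[str, ...] | str]  # OTU -> profile / status
    mean_rel: pd.DataFrame  # plants x OTUs mean relative abundance
    dropped: list[str] = field(default_factory=list)  # all-zero OTUs

    @property
    def included(self) -> list[str]:
        return [o for o, a in self.assignments.items() if isinstance(a, tuple)]


def build_profile_network(
    table: OtuTable,
    sample_plant: dict[str, str],
    metastats: dict[tuple[str, str], pd.DataFrame] | None = None,
    change_threshold: float = 0.01,
    ratio_threshold: float = 2.0,
    alpha: float = 0.05,
    label_info: pd.DataFrame | None = None,
) -> ProfileNetwork:
    """Assign plant-specific OTUs to habitat profiles.

    An OTU enters the network when its mean relative abundance changes by
    more than `change_threshold` (1% of the normalized dataset) between
    some pair of plants. Its "high" profile is the set of plants whose
    means lie within `ratio_threshold` of the top plant mean, accepted
    only if every high-set mean exceeds `ratio_threshold` times every
    excluded plant mean (the mean-read-ratio rule); OTUs that change but
    admit no such split are kept as "unassigned-altered".
    """
    rel = table.relative()
    plants = sorted(set(sample_plant.values()))
    if len(plants) < 2:
        raise ValueError("need at least two plants")
    mean_rel = rel.groupby(pd.Series(sample_plant)).mean().loc[plants]

    assignments: dict[str, tuple[str, ...] | str] = {}
    dropped: list[str] = []
    for otu in mean_rel.columns:
        m = mean_rel[otu]
        if float(m.max()) == 0.0:
            dropped.append(otu)
            continue
        if float(m.max() - m.min()) <= change_threshold:
            assignments[otu] = "excluded"
            continue
        top = float(m.max())
        high = [p for p in plants if m[p] * ratio_threshold >= top]
        low = [p for p in plants if p not in high]
        if low and all(
            m[h] > ratio_threshold * m[l] for h in high for l in low
        ):
            assignments[otu] = tuple(sorted(high))
        else:
            assignments[otu] = "unassigned-altered"

    g = nx.Graph()
    totals = table.counts.sum(axis=0) / table.counts.to_numpy().sum()
    for otu, assign in assignments.items():
        if not isinstance(assign, tuple):
            continue
        sig = _significance_flags(otu, metastats, alpha) if metastats else {}
        attrs = {
            "bipartite": "otu",
            "overall_rel_abundance": float(totals[otu]),
            "significant_pairs": ";".join(sorted(f"{a}|{b}" for a, b in sig)) or "",
        }
        if label_info is not None and otu in label_info.index:
            attrs["taxon_label"] = str(label_info.loc[otu, "nearest_reference"])
            attrs["label_confident"] = bool(label_info.loc[otu, "label_attached"])
        attrs["profile"] = ",".join(assign)
        g.add_node(otu, **attrs)
        for plant in assign:
            if not g.has_node(plant):
                g.add_node(plant, bipartite="profile")
            g.add_edge(otu, plant, weight=float(mean_rel.loc[plant, otu]))
    return ProfileNetwork(g, assignments, mean_rel, dropped)


def _significance_flags(
    otu: str, metastats: dict[tuple[str, str], pd.DataFrame], alpha: float
) -> set[tuple[str, str]]:
    flags = set()
    for pair, df in metastats.items():
        if otu in df.index and df.loc[otu, "q"] <= alpha:
            flags.add(tuple(sorted(pair)))
    return flags


def network_edge_list(net: ProfileNetwork) -> pd.DataFrame:
    rows = []
    for otu, assign in net.assignments.items():
        if isinstance(assign, tuple):
            for plant in assign:
                rows.append(
                    {
                        "otu": otu,
                        "profile": ",".join(assign),
                        "plant": plant,
                        "weight": float(net.mean_rel.loc[plant, otu]),
                    }
                )
    return pd.DataFrame(rows, columns=["otu", "profile", "plant", "weight"])
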