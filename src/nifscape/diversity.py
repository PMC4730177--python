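"""Alpha diversity on OTU count vectors: Shannon entropy (H', nats),
bias-corrected Chao1 richness, analytic rarefaction, Chao1 coverage, and
the group-comparison statistics used on diversity indices (Welch t,
Games-Howell with compact letter display)."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cluster import OtuTable


def _counts(x) -> np.ndarray:
    c = np.asarray(x, dtype=float)
    if c.ndim != 1 or (c < 0).any():
        raise ValueError("counts must be a 1-D non-negative vector")
    if c.sum() <= 0:
        raise ValueError("counts must not be all zero")
    return c[c > 0]


def shannon(counts) -> float:
    """Shannon index H' = -sum p_i ln p_i, in nats."""
    c = _counts(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    Well defined even without doubletons; equals S_obs when F1 <= 1.
    """
    c = _counts(counts)
    s_obs = len(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def coverage_pct(s_obs: float, chao1_value: float) -> float:
    """Observed richness as a percentage of Chao1-estimated richness."""
    if chao1_value <= 0:
        raise ValueError("chao1 must be > 0")
    return 100.0 * s_obs / chao1_value


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected OTU richness at each subsampling depth (hypergeometric).

    E[S_m] = sum_i [1 - C(N-N_i, m)/C(N, m)] for a draw of m reads
    without replacement from the N observed reads.
    """
    c = _counts(counts)
    n = int(c.sum())
    depths = np.asarray(depths, dtype=int)
    if (depths < 0).any() or (depths > n).any():
        raise ValueError("depths must lie in [0, total count]")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths), dtype=float)
    for k, m in enumerate(depths):
        keep = (n - c) >= m
        absent = np.zeros(len(c))
        absent[keep] = np.exp(log_comb(n - c[keep], m) - log_comb(n, m))
        out[k] = (1.0 - absent).sum()
    return out


def summarize(table: OtuTable) -> pd.DataFrame:
    """One diversity summary row per sample of an OTU table."""
    rows = []
    for sample in table.counts.index:
        c = table.counts.loc[sample].to_numpy()
        c = c[c > 0]
        ch = chao1(c)
        rows.append(
            {
                "sample": sample,
                "cutoff": table.cutoff,
                "S_obs": int(len(c)),
                "F1": int((c == 1).sum()),
                "F2": int((c == 2).sum()),
                "shannon": shannon(c),
                "chao1": ch,
                "coverage_pct": coverage_pct(len(c), ch),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons on diversity indices
# ---------------------------------------------------------------------------


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances); returns (t, p)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)


def games_howell(groups: dict[str, np.ndarray] | dict[str, list]) -> pd.DataFrame:
    """Games-Howell pairwise post-hoc test.

    For each pair: q = |m_i - m_j| / sqrt((v_i/n_i + v_j/n_j)/2), compared
    against the studentized range distribution with k groups and
    Welch-Satterthwaite degrees of freedom (floored at 1). Robust to
    unequal variances and sample sizes.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrs = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, a in arrs.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    k = len(names)
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        a, b = arrs[g1], arrs[g2]
        na, nb = len(a), len(b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / na + vb / nb
        if se2 == 0:
            q, df, p = 0.0, float(max(na + nb - 2, 1)), 1.0
        else:
            q = abs(a.mean() - b.mean()) / np.sqrt(se2 / 2.0)
            denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            df = max(se2**2 / denom, 1.0) if denom > 0 else 1.0
            p = float(stats.studentized_range.sf(q, k, df))
        rows.append({"group1": g1, "group2": g2, "q": float(q), "df": df, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


def compact_letter_display(pairs: pd.DataFrame, groups: list[str], alpha: float = 0.05) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    Greedy insert-absorb over the pairwise p-value table (columns group1,
    group2, p), the convention used to annotate bar plots of diversity
    and abundance comparisons.
    """
    sig = {
        frozenset((r.group1, r.group2)) for r in pairs.itertuples() if r.p <= alpha
    }
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, h)) not in sig for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb: drop sets fully contained in another
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(i != j and s < t for j, t in enumerate(letter_sets))
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for idx, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                out[g] += alphabet[idx % 26]
    return out
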