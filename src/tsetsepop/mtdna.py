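"""Diversity and differentiation statistics for aligned mtDNA sequences.

Implements haplotype diversity (Nei's unbiased Hd with its sampling
variance), the mean number of pairwise nucleotide differences K with Tajima's
total (sampling + stochastic, no recombination) variance, the per-site
nucleotide diversity Pi with Nei's variance, Hudson's F_ST / H_ST / K*_ST
differentiation statistics with sequence-permutation tests, and a simplified
statistical-parsimony haplotype network (minimum spanning network with a
user-supplied connection limit in mutational steps).

Sites containing N or a gap in any sequence are excluded before all
statistics (complete deletion); pass ``complete_deletion=False`` for
pairwise deletion of ambiguous sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .panels import SequencePanel

__all__ = [
    "HaplotypeTable", "SeqDiversityStats", "SeqDifferentiation",
    "HaplotypeNetwork", "collapse_haplotypes", "haplotype_diversity",
    "pairwise_differences", "sequence_diversity", "hudson_differentiation",
    "parsimony_network",
]


@dataclass
class HaplotypeTable:
    haplotypes: list[str]
    counts: pd.DataFrame         # haplotype index x population counts
    segregating_sites: list[int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1).to_numpy()


@dataclass
class SeqDiversityStats:
    n: int
    n_haplotypes: int
    s: int                       # segregating sites
    hd: float
    hd_variance: float
    pi: float
    pi_variance: float
    k: float
    k_total_variance: float
    length: int


@dataclass
class SeqDifferentiation:
    pop_a: str
    pop_b: str
    fst: float                   # Hudson 1 - Hw/Hb
    hst: float
    kst_star: float
    hs: float
    ht: float
    ks_star: float
    kt_star: float
    p_hst: float
    p_kst: float
    n_perm: int
    seed: int


@dataclass
class HaplotypeNetwork:
    nodes: list[str]             # haplotype ids + inferred intermediates
    edges: list[tuple[str, str, int]]
    components: list[list[str]]
    connection_limit: int


def _site_matrix(panel: SequencePanel, complete_deletion: bool = True):
    if complete_deletion:
        panel = panel.complete_sites()
    arr = np.array([list(s) for s in panel.sequences])
    return panel, arr


def collapse_haplotypes(panel: SequencePanel,
                        complete_deletion: bool = True) -> HaplotypeTable:
    """Collapse identical sequences (case-insensitive) into haplotypes."""
    panel, arr = _site_matrix(panel, complete_deletion)
    seqs = ["".join(row) for row in arr]
    uniq: dict[str, int] = {}
    for s in seqs:
        uniq.setdefault(s, len(uniq))
    pops = panel.population_names
    table = np.zeros((len(uniq), len(pops)), dtype=int)
    pop_idx = {p: i for i, p in enumerate(pops)}
    for s, p in zip(seqs, panel.populations):
        table[uniq[s], pop_idx[p]] += 1
    haps = list(uniq)
    seg = [i for i in range(arr.shape[1])
           if len(set(arr[:, i])) > 1]
    counts = pd.DataFrame(table, columns=pops,
                          index=[f"H{i + 1}" for i in range(len(haps))])
    return HaplotypeTable(haplotypes=haps, counts=counts,
                          segregating_sites=seg)


def haplotype_diversity(counts) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its sampling variance.

    Hd = n/(n-1) (1 - sum p_i^2); the variance is Nei's large-sample
    expression
    V(Hd) = 2/(n(n-1)) * [2(n-2) (sum p^3 - (sum p^2)^2) + sum p^2
            - (sum p^2)^2].
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    p = c / n
    s2 = (p ** 2).sum()
    s3 = (p ** 3).sum()
    hd = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2 ** 2)
                                 + s2 - s2 ** 2)
    return float(hd), float(max(var, 0.0))


def _pairwise_diff_stats(arr: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pairwise Hamming distance and the condensed distance vector."""
    n = arr.shape[0]
    enc = np.frombuffer("".join("".join(r) for r in arr).encode(),
                        dtype=np.uint8).reshape(n, -1)
    diffs = (enc[:, None, :] != enc[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, 1)
    vec = diffs[iu]
    return float(vec.mean()), diffs


def pairwise_differences(panel: SequencePanel,
                         complete_deletion: bool = True) -> dict:
    """K (mean pairwise differences), Tajima's total variance of K, and Pi
    (per-site) with Nei's sampling variance."""
    panel, arr = _site_matrix(panel, complete_deletion)
    n, L = arr.shape
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    if L == 0:
        raise ValueError("alignment length zero after site deletion")
    k, _ = _pairwise_diff_stats(arr)
    # Tajima's no-recombination total (sampling + stochastic) variance of K
    var_k = (3 * n * (n + 1) * k + 2 * (n ** 2 + n + 3) * k ** 2) \
        / (11 * (n ** 2 - 7 * n + 6))
    pi = k / L
    # Nei's variance of pi for a sample of n sequences, no recombination
    var_pi = (n + 1) * pi / (3 * (n - 1) * L) \
        + 2 * (n ** 2 + n + 3) * pi ** 2 / (9 * n * (n - 1))
    return {"k": k, "k_total_variance": float(var_k), "pi": float(pi),
            "pi_variance": float(var_pi), "n": n, "length": L}


def sequence_diversity(panel: SequencePanel, population: str | None = None,
                       complete_deletion: bool = True) -> SeqDiversityStats:
    if population is not None:
        panel = panel.subset_populations([population])
    table = collapse_haplotypes(panel, complete_deletion)
    counts = table.total_counts()
    hd, hd_var = haplotype_diversity(counts)
    pw = pairwise_differences(panel, complete_deletion)
    return SeqDiversityStats(
        n=int(counts.sum()), n_haplotypes=len(counts),
        s=len(table.segregating_sites), hd=hd, hd_variance=hd_var,
        pi=pw["pi"], pi_variance=pw["pi_variance"], k=pw["k"],
        k_total_variance=pw["k_total_variance"], length=pw["length"])


# --------------------------------------------------------------------------
# Hudson differentiation
# --------------------------------------------------------------------------

def _hst_kst(diffs: np.ndarray, groups: np.ndarray, weights_cache=None
             ) -> tuple[float, float, float, float, float, float]:
    """(fst, hst, kst*, hs, ht, ks*) from a pairwise-difference matrix and
    binary group labels."""
    n = len(groups)
    iu = np.triu_indices(n, 1)
    same = groups[iu[0]] == groups[iu[1]]
    d = diffs[iu]
    # Hudson eq-3 Fst: 1 - mean within / mean between
    hw_terms = []
    for g in (0, 1):
        m = (groups[iu[0]] == g) & (groups[iu[1]] == g)
        if m.any():
            hw_terms.append(d[m].mean())
    hb = d[~same].mean() if (~same).any() else np.nan
    fst = 1.0 - np.mean(hw_terms) / hb if hw_terms and hb and hb > 0 \
        else np.nan

    # haplotype-frequency based Hst (weights n_i / n)
    hs_parts, w_parts = [], []
    for g in (0, 1):
        idx = np.where(groups == g)[0]
        if idx.size < 2:
            continue
        sub = diffs[np.ix_(idx, idx)]
        # haplotype diversity from identity classes of the distance matrix
        hs_parts.append(_hd_from_diffs(sub))
        w_parts.append(idx.size)
    w = np.asarray(w_parts, dtype=float)
    hs = float((w / w.sum() * np.asarray(hs_parts)).sum()) if len(w) else np.nan
    ht = _hd_from_diffs(diffs)
    hst = 1.0 - hs / ht if ht and ht > 0 else np.nan

    # K*st: log-corrected mean differences, K*_S weighted by C(n_i, 2)
    ks_parts, wk_parts = [], []
    logd = np.log(1.0 + d)
    for g in (0, 1):
        m = (groups[iu[0]] == g) & (groups[iu[1]] == g)
        if m.any():
            ks_parts.append(logd[m].mean())
            wk_parts.append(m.sum())
    wk = np.asarray(wk_parts, dtype=float)
    ks = float((wk / wk.sum() * np.asarray(ks_parts)).sum()) \
        if len(wk) else np.nan
    kt = float(logd.mean())
    kst = 1.0 - ks / kt if kt and kt > 0 else np.nan
    return fst, hst, kst, hs, ht, ks, kt


def _hd_from_diffs(sub: np.ndarray) -> float:
    """Unbiased haplotype diversity of a sample given its 0-distance classes."""
    n = sub.shape[0]
    same = sub == 0
    # class sizes: count of identical sequences per row, deduplicated
    seen = np.zeros(n, dtype=bool)
    counts = []
    for i in range(n):
        if seen[i]:
            continue
        members = np.where(same[i])[0]
        seen[members] = True
        counts.append(len(members))
    p = np.asarray(counts, dtype=float) / n
    return float(n / (n - 1) * (1.0 - (p ** 2).sum()))


def hudson_differentiation(panel: SequencePanel, pop_a: str, pop_b: str,
                           n_perm: int = 10000, seed: int = 0,
                           complete_deletion: bool = True
                           ) -> SeqDifferentiation:
    """Hudson F_ST, H_ST and K*_ST for one population pair with permutation
    tests (sequences reassigned to localities)."""
    sub = panel.subset_populations([pop_a, pop_b])
    sub, arr = _site_matrix(sub, complete_deletion)
    groups = np.array([0 if p == pop_a else 1 for p in sub.populations])
    if (groups == 0).sum() < 2 or (groups == 1).sum() < 2:
        raise ValueError("both populations need n >= 2")
    _, diffs = _pairwise_diff_stats(arr)
    if diffs.max() == 0:
        raise ValueError("pooled sample monomorphic: statistics undefined")
    fst, hst, kst, hs, ht, ks, kt = _hst_kst(diffs, groups)
    rng = np.random.default_rng(seed)
    ge_h = ge_k = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        _, h_null, k_null, *_ = _hst_kst(diffs, perm)
        if h_null >= hst:
            ge_h += 1
        if k_null >= kst:
            ge_k += 1
    p_h = (ge_h + 1) / (n_perm + 1)
    p_k = (ge_k + 1) / (n_perm + 1)
    return SeqDifferentiation(pop_a=pop_a, pop_b=pop_b, fst=float(fst),
                              hst=float(hst), kst_star=float(kst),
                              hs=float(hs), ht=float(ht), ks_star=float(ks),
                              kt_star=float(kt), p_hst=float(p_h),
                              p_kst=float(p_k), n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------------
# haplotype network
# --------------------------------------------------------------------------

def parsimony_network(table: HaplotypeTable,
                      connection_limit: int = 11) -> HaplotypeNetwork:
    """Minimum-spanning haplotype network.

    Edges longer than the connection limit are removed (disconnecting the
    network); edges of more than one step gain inferred intermediate nodes.
    """
    if connection_limit < 1:
        raise ValueError("connection limit must be >= 1")
    haps = table.haplotypes
    names = list(table.counts.index)
    m = len(haps)
    g = nx.Graph()
    g.add_nodes_from(names)
    arrs = [np.frombuffer(h.encode(), dtype=np.uint8) for h in haps]
    for i in range(m):
        for j in range(i + 1, m):
            steps = int((arrs[i] != arrs[j]).sum())
            g.add_edge(names[i], names[j], weight=steps)
    mst = nx.minimum_spanning_tree(g, weight="weight") if m > 1 else g
    edges = []
    net = nx.Graph()
    net.add_nodes_from(names)
    inferred = 0
    for u, v, data in sorted(mst.edges(data=True)):
        w = int(data["weight"])
        if w > connection_limit:
            continue
        if w <= 1:
            edges.append((u, v, w))
            net.add_edge(u, v)
        else:
            prev = u
            for s in range(1, w):
                inferred += 1
                mid = f"i{inferred}"
                net.add_node(mid)
                edges.append((prev, mid, 1))
                net.add_edge(prev, mid)
                prev = mid
            edges.append((prev, v, 1))
            net.add_edge(prev, v)
    components = [sorted(c) for c in nx.connected_components(net)]
    components.sort()
    return HaplotypeNetwork(nodes=sorted(net.nodes), edges=edges,
                            components=components,
                            connection_limit=connection_limit)
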