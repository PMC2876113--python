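"""Cavalli-Sforza & Edwards chord distance and Neighbour-Joining trees.

The chord distance treats allele-frequency vectors as points on a
hypersphere: per locus cos(theta_l) = sum_a sqrt(p_a q_a), and the distance
combines loci as D = sqrt( (1/L) * sum_l 2 (1 - cos theta_l) ). Classic
software differs in whether a 2/pi prefactor (arc-length normalization) is
applied; both conventions are exposed (default: no prefactor).

NJ follows Saitou & Nei's Q-criterion with deterministic tie-breaking by
label order; negative branch lengths are clamped to zero with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panels import DistanceMatrix, GenotypePanel

__all__ = ["FrequencyTable", "PopulationTree", "frequency_table",
           "chord_distance", "chord_distance_matrix", "neighbor_joining",
           "to_newick"]


@dataclass
class FrequencyTable:
    populations: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]   # (pop, locus) -> {allele: p}

    def vector_pair(self, locus: str, pop_a: str, pop_b: str):
        fa = self.freqs.get((pop_a, locus))
        fb = self.freqs.get((pop_b, locus))
        if not fa or not fb:
            return None
        alleles = sorted(set(fa) | set(fb))
        return (np.array([fa.get(a, 0.0) for a in alleles]),
                np.array([fb.get(a, 0.0) for a in alleles]))


def frequency_table(panel: GenotypePanel) -> FrequencyTable:
    """Missing-aware allele frequencies (X-linked males single-counted)."""
    freqs = {}
    for pop in panel.population_names:
        idx = panel.individuals_in(pop)
        for l, locus in enumerate(panel.loci):
            counts = panel.allele_counts(l, individuals=idx)
            tot = sum(counts.values())
            if tot == 0:
                continue
            freqs[(pop, locus)] = {a: c / tot for a, c in counts.items()}
    return FrequencyTable(populations=panel.population_names,
                          loci=list(panel.loci), freqs=freqs)


def chord_distance(table: FrequencyTable, pop_a: str, pop_b: str,
                   arc_prefactor: bool = False) -> float:
    terms = []
    for locus in table.loci:
        pair = table.vector_pair(locus, pop_a, pop_b)
        if pair is None:
            continue
        pa, pb = pair
        cos_t = np.clip(np.sqrt(pa * pb).sum(), 0.0, 1.0)
        terms.append(2.0 * (1.0 - cos_t))
    if not terms:
        raise ValueError(f"no shared loci between {pop_a} and {pop_b}")
    d = float(np.sqrt(np.mean(terms)))
    if arc_prefactor:
        d *= 2.0 / np.pi
    return d


def chord_distance_matrix(panel: GenotypePanel,
                          arc_prefactor: bool = False) -> DistanceMatrix:
    table = frequency_table(panel)
    pops = panel.population_names
    m = len(pops)
    vals = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            vals[i, j] = vals[j, i] = chord_distance(
                table, pops[i], pops[j], arc_prefactor)
    return DistanceMatrix(pops, vals, statistic="chord")


# --------------------------------------------------------------------------
# neighbour joining
# --------------------------------------------------------------------------

@dataclass
class TreeNodeRec:
    name: str | None
    children: list = field(default_factory=list)   # (node, branch_length)


@dataclass
class PopulationTree:
    root: TreeNodeRec
    labels: list[str]
    clamped_branches: int = 0      # negative NJ lengths clamped to 0


def neighbor_joining(dm: DistanceMatrix) -> PopulationTree:
    """Saitou-Nei NJ; ties in the Q-criterion break toward the pair whose
    labels sort first."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if not np.allclose(dm.values, dm.values.T, atol=1e-12):
        raise ValueError("distance matrix not symmetric")
    D = dm.values.astype(float).copy()
    nodes = [TreeNodeRec(name=l) for l in dm.labels]
    names = list(dm.labels)                   # sort keys for tie-breaking
    clamped = 0
    while len(nodes) > 3:
        m = len(nodes)
        row_sums = D.sum(axis=1)
        Q = (m - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        cand = [(i, j) for i, j in cand if i < j]
        i, j = min(cand, key=lambda ij: tuple(sorted(
            (names[ij[0]], names[ij[1]]))))
        li = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            lj, clamped = 0.0, clamped + 1
        new = TreeNodeRec(name=None,
                          children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:m - 2, :m - 2] = D[np.ix_(keep, keep)]
        D2[-1, :m - 2] = dnew[keep]
        D2[:m - 2, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
    # join the final three nodes at an internal node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    b0 = 0.5 * (d01 + d02 - d12)
    b1 = 0.5 * (d01 + d12 - d02)
    b2 = 0.5 * (d02 + d12 - d01)
    lens = []
    for b in (b0, b1, b2):
        if b < 0:
            b, clamped = 0.0, clamped + 1
        lens.append(b)
    root = TreeNodeRec(name=None, children=[(nodes[k], lens[k])
                                            for k in range(3)])
    return PopulationTree(root=root, labels=list(dm.labels),
                          clamped_branches=clamped)


def to_newick(tree: PopulationTree) -> str:
    def render(node: TreeNodeRec) -> str:
        if not node.children:
            return node.name
        inner = ",".join(f"{render(c)}:{bl:.10g}" for c, bl in node.children)
        return f"({inner})"
    return render(tree.root) + ";"


def tip_branch_lengths(tree: PopulationTree) -> dict[str, float]:
    out = {}

    def walk(node):
        for child, bl in node.children:
            if not child.children:
                out[child.name] = bl
            walk(child)
    walk(tree.root)
    return out
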