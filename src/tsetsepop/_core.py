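"""Moment-estimator machinery shared by the F-statistic modules.

The F-statistics are estimated from variance components of a nested
random-effects ANOVA on gamete-level allele indicators (Henderson method-1
moment equations on the uncorrected sums of squares). For the two-level
design (gamete < individual < population) this reproduces the Weir-Cockerham
(1984) a/b/c components exactly; adding a region level above populations gives
the hierarchical F-statistics.

Everything here works on dosage matrices: for one locus, ``dosage[i, a]`` is
the number of copies of allele ``a`` carried by (diploid) individual ``i``.
Individuals missing at the locus must be filtered out by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = ["anova_components", "dosage_matrix", "g_statistic",
           "genotype_codes", "f_stat_from_components"]


def dosage_matrix(calls_locus: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosages for one locus from an ``(n, 2)`` diploid call slice.

    Returns ``(dosage, alleles, scored)`` where ``scored`` flags individuals
    with a complete diploid call. Hemizygous (single-slot) calls are treated
    as unscored here — callers wanting the pseudo-homozygous coding must pass
    a ``diff_view`` panel.
    """
    a, b = calls_locus[:, 0], calls_locus[:, 1]
    scored = (a > 0) & (b > 0)
    alleles = np.unique(np.concatenate([a[scored], b[scored]]))
    if alleles.size == 0:
        return np.zeros((0, 0), dtype=np.int64), alleles, scored
    dos = ((a[scored, None] == alleles[None, :]).astype(np.int64)
           + (b[scored, None] == alleles[None, :]).astype(np.int64))
    return dos, alleles, scored


def _group_sizes(codes: np.ndarray) -> np.ndarray:
    return np.bincount(codes)


def anova_components(dosage: np.ndarray, levels: list[np.ndarray]) -> np.ndarray:
    """Variance components per allele for a nested gametic ANOVA.

    Parameters
    ----------
    dosage
        ``(n, A)`` allele dosages for the n scored diploid individuals.
    levels
        Nested grouping codes, coarsest first (e.g. ``[region, population]``),
        each an ``(n,)`` integer array with contiguous codes starting at 0 and
        codes at finer levels unique across coarser groups. The individual and
        gamete levels are implicit.

    Returns
    -------
    ``(A, len(levels) + 2)`` array of components, ordered coarsest group
    effect first, then between-individual, then within-individual (residual).
    """
    n, A = dosage.shape
    if n == 0 or A == 0:
        return np.zeros((A, len(levels) + 2))
    N = 2 * n                      # gametes
    K = len(levels)
    n_eff = K + 2                  # group effects + individual + residual

    # uncorrected sums T_l per allele, for grand + each grouping + ind + obs
    tot = dosage.sum(axis=0).astype(float)              # (A,)
    T = [tot ** 2 / N]                                  # grand
    for codes in levels:
        gs = np.zeros((codes.max() + 1, A))
        np.add.at(gs, codes, dosage)
        sizes = 2.0 * _group_sizes(codes)
        T.append((gs ** 2 / sizes[:, None]).sum(axis=0))
    T.append((dosage.astype(float) ** 2 / 2.0).sum(axis=0))   # individual
    T.append(tot.astype(float))                               # observation

    # coefficient matrix: rows are groupings (grand, levels 1..K, individual,
    # observation), columns the random effects (levels 1..K, individual,
    # residual). C[l, m] = sum over groups g of row l of
    # (sum of squared sizes of effect-m groups inside g) / size(g),
    # sizes in gametes; when the effect is coarser than or equal to the row
    # this collapses to N.
    row_codes = [np.zeros(n, dtype=int)] + list(levels) + [np.arange(n)]
    n_rows = K + 3                                       # + observation row
    C = np.full((n_rows, n_eff), float(N))
    for l in range(K + 2):                               # obs row stays N
        member = row_codes[l]
        sizes_l = _group_sizes(member)                   # individuals/group
        n_groups = len(sizes_l)
        row_depth = l
        for m in range(n_eff):
            eff_depth = m + 1 if m < K else (K + 1 if m == K else K + 2)
            if eff_depth <= row_depth:
                continue                                 # stays N
            if m == K + 1:                               # residual effect
                C[l, m] = float(n_groups)
            elif m == K:                                 # individual effect
                C[l, m] = 2.0 * n_groups
            else:                                        # finer grouping
                fine = levels[m]
                gs_fine = 2.0 * _group_sizes(fine)
                per_coarse = np.zeros(n_groups)
                owner = _first_occurrence_map(fine, member)
                np.add.at(per_coarse, owner, gs_fine ** 2)
                C[l, m] = (per_coarse / (2.0 * sizes_l)).sum()

    M = C[1:, :] - C[:-1, :]                             # (K+2, K+2)
    t = np.stack(T, axis=0)                              # (K+3, A)
    rhs = t[1:, :] - t[:-1, :]
    comps = np.linalg.solve(M, rhs)                      # (K+2, A)
    return comps.T


def _first_occurrence_map(fine: np.ndarray, coarse: np.ndarray) -> np.ndarray:
    """For each fine-group code, the coarse-group code containing it."""
    out = np.zeros(fine.max() + 1, dtype=int)
    out[fine] = coarse
    return out


def f_stat_from_components(comps: np.ndarray) -> dict[str, float]:
    """Two-level ratios from summed (a, b, c) components."""
    a, b, c = comps
    tot = a + b + c
    return {
        "theta": a / tot if tot != 0 else np.nan,
        "f": b / (b + c) if (b + c) != 0 else np.nan,
        "F": (a + b) / tot if tot != 0 else np.nan,
    }


def genotype_codes(calls_locus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer genotype codes (order-free pairs) for one locus.

    Returns ``(codes, scored)``; unscored individuals get code -1.
    """
    a = np.minimum(calls_locus[:, 0], calls_locus[:, 1])
    b = np.maximum(calls_locus[:, 0], calls_locus[:, 1])
    scored = a > 0
    pairs = np.stack([a, b], axis=1)
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    codes = np.where(scored, inv, -1)
    return codes, scored


def g_statistic(table: np.ndarray) -> float:
    """Likelihood-ratio G for a contingency table (zero cells skipped)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())
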