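"""Locus quality diagnostics: null-allele frequency, the expected-blanks
binomial test, pairwise linkage-disequilibrium permutation tests, the
significant-test-count binomial check, and Holm's sequential correction.

Null-allele frequency is estimated per locus (pooled across populations by
default, per population on request) under the model of Brookfield's second
estimator: Hardy-Weinberg proportions with one non-amplifying allele at
frequency ``p_n``, blanks being null homozygotes and apparent homozygotes
including visible/null heterozygotes. The estimate maximizes the trinomial
likelihood of (heterozygotes, apparent homozygotes, blanks); it is solved
numerically and clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ._core import g_statistic, genotype_codes
from .panels import GenotypePanel

__all__ = [
    "NullAlleleEstimate", "LDTestResult",
    "brookfield2_null_frequency", "null_allele_table",
    "expected_blanks_test", "ld_pairwise_tests",
    "significant_count_binomial", "holm_correction",
    "major_allele_filter",
]


@dataclass
class NullAlleleEstimate:
    locus: str
    population: str                     # "pooled" for the default mode
    p_n: float
    method: str                         # brookfield2 | x_missing_proportion
    n_individuals: int
    observed_blanks: int
    expected_blanks: float
    undefined: bool = False


def _class_counts(panel: GenotypePanel, locus: int,
                  individuals: np.ndarray) -> tuple[int, int, int, float]:
    """(het, visible homozygote, blank, He') among diploid-scored females +
    autosomal individuals; X-linked loci use females only."""
    calls = panel.calls[individuals, locus, :]
    if panel.x_linked[locus]:
        females = panel.sex[individuals] == "F"
        calls = calls[females]
    a, b = calls[:, 0], calls[:, 1]
    scored = (a > 0) & (b > 0)
    het = int(((a != b) & scored).sum())
    hom = int(((a == b) & scored).sum())
    blank = int((~scored).sum())
    vals = np.concatenate([a[scored], b[scored]])
    if vals.size == 0:
        return het, hom, blank, np.nan
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    he = 1.0 - (p ** 2).sum()
    return het, hom, blank, float(he)


def brookfield2_null_frequency(panel: GenotypePanel, locus,
                               individuals: np.ndarray | None = None,
                               population: str = "pooled",
                               ) -> NullAlleleEstimate:
    """Brookfield estimator-2 null frequency for one locus.

    Solves for ``p_n`` in the HWE-with-null model using both the heterozygote
    deficit and the observed blank count.
    """
    if isinstance(locus, str):
        locus = panel.loci.index(locus)
    if individuals is None:
        individuals = np.arange(panel.n_individuals)
    het, hom, blank, he = _class_counts(panel, locus, individuals)
    n = het + hom + blank
    name = panel.loci[locus]
    if n == 0 or not np.isfinite(he):
        return NullAlleleEstimate(name, population, np.nan, "brookfield2",
                                  n, blank, np.nan, undefined=True)
    if het + hom == 0:
        pn = 1.0
    else:
        def negloglik(r):
            p_het = (1 - r) ** 2 * he
            p_blank = r ** 2
            p_hom = 1.0 - p_het - p_blank
            eps = 1e-12
            ll = het * np.log(max(p_het, eps)) + hom * np.log(max(p_hom, eps))
            if blank:
                ll += blank * np.log(max(p_blank, eps))
            return -ll
        res = optimize.minimize_scalar(negloglik, bounds=(0.0, 1.0),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        pn = float(np.clip(res.x, 0.0, 1.0))
        if blank == 0 and pn < 1e-6:
            pn = 0.0
    expected = _expected_blank_count(panel, locus, individuals, pn)
    return NullAlleleEstimate(name, population, pn, "brookfield2", n,
                              blank, expected)


def x_missing_null_frequency(panel: GenotypePanel, locus,
                             individuals: np.ndarray | None = None,
                             population: str = "pooled") -> NullAlleleEstimate:
    """Direct null-frequency estimate for X-linked loci: the proportion of
    missing genotypes among hemizygous males."""
    if isinstance(locus, str):
        locus = panel.loci.index(locus)
    if not panel.x_linked[locus]:
        raise ValueError("x_missing_proportion applies to X-linked loci only")
    if individuals is None:
        individuals = np.arange(panel.n_individuals)
    males = individuals[panel.sex[individuals] == "M"]
    name = panel.loci[locus]
    if males.size == 0:
        return NullAlleleEstimate(name, population, np.nan,
                                  "x_missing_proportion", 0, 0, np.nan,
                                  undefined=True)
    blanks = int((panel.calls[males, locus, 0] == 0).sum())
    pn = blanks / males.size
    return NullAlleleEstimate(name, population, pn, "x_missing_proportion",
                              int(males.size), blanks, float(blanks))


def null_allele_table(panel: GenotypePanel, per_population: bool = False,
                      ) -> list[NullAlleleEstimate]:
    out = []
    if per_population:
        for pop in panel.population_names:
            idx = panel.individuals_in(pop)
            for l in range(panel.n_loci):
                out.append(brookfield2_null_frequency(panel, l, idx, pop))
    else:
        for l in range(panel.n_loci):
            out.append(brookfield2_null_frequency(panel, l))
    return out


def _expected_blank_count(panel: GenotypePanel, locus: int,
                          individuals: np.ndarray, pn: float) -> float:
    """Expected blanks: p_n^2 per diploid, p_n per hemizygous male."""
    if not np.isfinite(pn):
        return np.nan
    males = panel.sex[individuals] == "M"
    if panel.x_linked[locus]:
        n_m = int(males.sum())
        n_f = int((~males).sum())
        return n_m * pn + n_f * pn ** 2
    return len(individuals) * pn ** 2


def expected_blanks_test(panel: GenotypePanel,
                         estimates: list[NullAlleleEstimate]) -> dict:
    """Exact unilateral binomial test, H1: fewer blanks than expected.

    Pools loci: the per-individual blank probability at each locus comes from
    that locus's ``p_n`` (p_n^2 for diploids, p_n for hemizygous males); the
    pooled expected probability is the mean over individual x locus cells.
    """
    by_locus = {e.locus: e for e in estimates if not e.undefined}
    total_cells = 0
    total_expected = 0.0
    observed = 0
    for l, name in enumerate(panel.loci):
        est = by_locus.get(name)
        if est is None:
            continue
        idx = np.arange(panel.n_individuals)
        total_cells += len(idx)
        total_expected += _expected_blank_count(panel, l, idx, est.p_n)
        observed += int((panel.calls[:, l, 0] == 0).sum())
    if total_cells == 0:
        raise ValueError("no usable null-frequency estimates")
    p_blank = min(total_expected / total_cells, 1.0)
    if p_blank == 0.0:
        pval = 1.0
    else:
        pval = float(stats.binom.cdf(observed, total_cells, p_blank))
    return {"observed": observed, "expected": total_expected,
            "n_cells": total_cells, "p_blank": p_blank, "p_value": pval}


# --------------------------------------------------------------------------
# linkage disequilibrium
# --------------------------------------------------------------------------

@dataclass
class LDTestResult:
    locus_a: str
    locus_b: str
    g: float
    n_perm: int
    seed: int
    p_value: float


def major_allele_filter(panel: GenotypePanel, threshold: float = 0.9,
                        ) -> tuple[list[str], list[tuple[str, str]]]:
    """Loci kept / excluded (with reason) by the major-allele-frequency rule."""
    keep, dropped = [], []
    for l, name in enumerate(panel.loci):
        counts = panel.allele_counts(l)
        tot = sum(counts.values())
        if tot == 0:
            dropped.append((name, "no scored genotypes"))
            continue
        major = max(counts.values()) / tot
        if major > threshold:
            dropped.append((name,
                            f"major allele frequency {major:.3f} > {threshold}"))
        else:
            keep.append(name)
    return keep, dropped


def ld_pairwise_tests(panel: GenotypePanel, n_perm: int = 10000,
                      seed: int = 0, major_threshold: float = 0.9,
                      ) -> tuple[list[LDTestResult], list[tuple[str, str]]]:
    """G-based LD permutation test for every informative locus pair.

    Genotypes at the second locus are permuted among individuals within each
    subsample (free recombination null); G is summed over subsamples. Males
    are coded homozygous at X-linked loci.
    """
    keep, dropped = major_allele_filter(panel, major_threshold)
    if len(keep) < 2:
        return [], dropped
    view = panel.diff_view()
    groups, _ = _pop_codes_local(panel)
    n_groups = groups.max() + 1
    name_to_idx = {n: i for i, n in enumerate(panel.loci)}
    results = []
    master = np.random.default_rng(seed)
    for la, lb in combinations(sorted(keep), 2):
        ia, ib = name_to_idx[la], name_to_idx[lb]
        rng = np.random.default_rng(master.integers(2 ** 31))
        ca, sa = genotype_codes(view.calls[:, ia])
        cb, sb = genotype_codes(view.calls[:, ib])
        both = sa & sb
        obs = _ld_g(ca, cb, groups, both, n_groups)
        null = np.empty(n_perm)
        idx_by_group = [np.where(both & (groups == g))[0]
                        for g in range(n_groups)]
        cb_perm = cb.copy()
        for b in range(n_perm):
            for idx in idx_by_group:
                cb_perm[idx] = cb[idx][rng.permutation(len(idx))]
            null[b] = _ld_g(ca, cb_perm, groups, both, n_groups)
        p = (np.sum(null >= obs) + 1) / (n_perm + 1)
        results.append(LDTestResult(la, lb, float(obs), n_perm, seed,
                                    float(p)))
    return results, dropped


def _ld_g(ca, cb, groups, mask, n_groups) -> float:
    g = 0.0
    for grp in range(n_groups):
        m = mask & (groups == grp)
        if m.sum() < 2:
            continue
        a, b = ca[m], cb[m]
        table = np.zeros((a.max() + 1, b.max() + 1))
        np.add.at(table, (a, b), 1)
        g += g_statistic(table)
    return g


def _pop_codes_local(panel: GenotypePanel) -> tuple[np.ndarray, list[str]]:
    names = panel.population_names
    lookup = {p: i for i, p in enumerate(names)}
    return np.array([lookup[p] for p in panel.populations]), names


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def significant_count_binomial(n_significant: int, n_tests: int,
                               alpha: float = 0.05) -> float:
    """Exact one-sided binomial P that the significant-test proportion
    exceeds alpha (upper tail at the observed count)."""
    if not 0 <= n_significant <= n_tests:
        raise ValueError("need 0 <= n_significant <= n_tests")
    return float(stats.binom.sf(n_significant - 1, n_tests, alpha))


def holm_correction(p_values, alpha: float = 0.05):
    """Holm step-down decisions and monotone adjusted P-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("P-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted
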