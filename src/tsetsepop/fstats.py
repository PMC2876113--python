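"""Weir-Cockerham and hierarchical F-statistics with permutation tests.

Estimators are moment (ANOVA) estimators on gamete-level allele indicators;
multi-allelic and multi-locus estimates combine variance components by
summation before taking ratios (never by averaging per-locus ratios).

X-linked loci follow the study conventions: hemizygous males are excluded
from inbreeding (f) estimates and re-coded as homozygous diploids for
differentiation statistics and their permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._core import anova_components, dosage_matrix, g_statistic, genotype_codes
from .panels import GenotypePanel

__all__ = [
    "FStatEstimates", "HierarchicalFStats", "PermutationTestResult",
    "weir_cockerham", "hierarchical_fstats", "permutation_test",
    "fstat_confidence_intervals", "nei_gene_diversity",
    "compare_region_diversity",
]


@dataclass
class FStatEstimates:
    loci: list[str]
    per_locus: pd.DataFrame          # columns f, theta, F (NaN if undefined)
    overall: dict[str, float]
    components_diff: np.ndarray      # (L, 3) a, b, c from the diff view
    components_fis: np.ndarray       # (L, 2) b, c from the f view


@dataclass
class HierarchicalFStats:
    levels: list[str]                # e.g. ["region", "population"]
    F_IS: float
    F_SR: float
    F_RT: float
    F_ST: float
    F_IT: float
    components: np.ndarray           # summed (region, pop, ind, resid)
    per_locus_components: np.ndarray


@dataclass
class PermutationTestResult:
    observed: float
    statistic: str                   # "f" or "G"
    scheme: str
    n_perm: int
    seed: int
    p_value: float
    null_values: np.ndarray = field(repr=False, default=None)


def _pop_codes(panel: GenotypePanel, individuals=None) -> tuple[np.ndarray, list[str]]:
    pops = panel.populations if individuals is None else \
        [panel.populations[i] for i in individuals]
    names = panel.population_names
    lookup = {p: i for i, p in enumerate(names)}
    return np.array([lookup[p] for p in pops]), names


def _locus_components(calls_locus: np.ndarray, groups: np.ndarray,
                      n_levels_expected: int,
                      extra_levels: list[np.ndarray] | None = None) -> np.ndarray:
    """Summed-over-alleles components for one locus (zeros if uninformative)."""
    dos, alleles, scored = dosage_matrix(calls_locus)
    if alleles.size < 2:
        return np.zeros(n_levels_expected)
    levels = []
    if extra_levels:
        for lv in extra_levels:
            levels.append(lv[scored])
    levels.append(groups[scored])
    levels = [_recode_nested(levels, i) for i in range(len(levels))]
    comps = anova_components(dos, levels)
    return comps.sum(axis=0)


def _recode_nested(levels: list[np.ndarray], i: int) -> np.ndarray:
    """Contiguous codes for level i, unique within coarser groups."""
    key = np.stack([levels[j] for j in range(i + 1)], axis=1)
    _, codes = np.unique(key, axis=0, return_inverse=True)
    return codes


def weir_cockerham(panel: GenotypePanel, grouping: str = "population") -> FStatEstimates:
    """Weir-Cockerham f (F_IS), theta (F_ST) and F (F_IT).

    With a single group only f is defined. ``grouping`` may be "population"
    or "region".
    """
    if grouping == "population":
        groups, _ = _pop_codes(panel)
    elif grouping == "region":
        regs = panel.region_of_individual
        names = sorted(set(regs))
        groups = np.array([names.index(r) for r in regs])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    n_groups = groups.max() + 1

    fis_panel = panel.fis_view()
    diff_panel = panel.diff_view()
    L = panel.n_loci
    comp_diff = np.zeros((L, 3))
    comp_fis = np.zeros((L, 2))
    rows = []
    for l in range(L):
        if n_groups >= 2:
            comp_diff[l] = _locus_components(diff_panel.calls[:, l], groups, 3)
            cf = _locus_components(fis_panel.calls[:, l], groups, 3)
            comp_fis[l] = cf[1:]
        else:
            comp_fis[l] = _single_group_components(fis_panel.calls[:, l])
        a, b, c = comp_diff[l]
        bf, cf_ = comp_fis[l]
        rows.append({
            "locus": panel.loci[l],
            "f": bf / (bf + cf_) if (bf + cf_) != 0 else np.nan,
            "theta": a / (a + b + c) if n_groups >= 2 and (a + b + c) != 0 else np.nan,
            "F": (a + b) / (a + b + c) if n_groups >= 2 and (a + b + c) != 0 else np.nan,
        })
    per_locus = pd.DataFrame(rows).set_index("locus")
    A, B, Cc = comp_diff.sum(axis=0)
    Bf, Cf = comp_fis.sum(axis=0)
    overall = {
        "f": Bf / (Bf + Cf) if (Bf + Cf) != 0 else np.nan,
        "theta": A / (A + B + Cc) if n_groups >= 2 and (A + B + Cc) != 0 else np.nan,
        "F": (A + B) / (A + B + Cc) if n_groups >= 2 and (A + B + Cc) != 0 else np.nan,
    }
    return FStatEstimates(loci=list(panel.loci), per_locus=per_locus,
                          overall=overall, components_diff=comp_diff,
                          components_fis=comp_fis)


def _single_group_components(calls_locus: np.ndarray) -> np.ndarray | None:
    dos, alleles, scored = dosage_matrix(calls_locus)
    if alleles.size < 2:
        return np.zeros(2)
    comps = anova_components(dos, [])
    return comps.sum(axis=0)


def hierarchical_fstats(panel: GenotypePanel,
                        hierarchy: tuple[str, str] = ("region", "population"),
                        ) -> HierarchicalFStats:
    """Nested moment estimators for individuals < populations < regions.

    A single-level hierarchy ("population",) reduces exactly to the two-level
    Weir-Cockerham estimates.
    """
    diff_panel = panel.diff_view()
    pop_codes, _ = _pop_codes(panel)
    if tuple(hierarchy) == ("population",):
        wc = weir_cockerham(panel)
        A, B, C = wc.components_diff.sum(axis=0)
        tot = A + B + C
        return HierarchicalFStats(
            levels=["population"], F_IS=wc.overall["f"],
            F_SR=np.nan, F_RT=np.nan,
            F_ST=wc.overall["theta"], F_IT=wc.overall["F"],
            components=np.array([A, B, C]),
            per_locus_components=wc.components_diff)
    if tuple(hierarchy) != ("region", "population"):
        raise ValueError("hierarchy must be ('region','population') "
                         "or ('population',)")
    regs = panel.region_of_individual
    region_names = sorted(set(regs))
    if len(region_names) < 2:
        # collapsed region level: reduces exactly to the two-level estimates
        wc = weir_cockerham(panel)
        A, B, C = wc.components_diff.sum(axis=0)
        tot = A + B + C
        return HierarchicalFStats(
            levels=["population"], F_IS=wc.overall["f"],
            F_SR=wc.overall["theta"], F_RT=np.nan,
            F_ST=wc.overall["theta"], F_IT=wc.overall["F"],
            components=np.array([0.0, A, B, C]),
            per_locus_components=wc.components_diff)
    reg_codes = np.array([region_names.index(r) for r in regs])

    L = panel.n_loci
    comps = np.zeros((L, 4))         # region, pop, individual, residual
    for l in range(L):
        comps[l] = _locus_components(diff_panel.calls[:, l], pop_codes, 4,
                                     extra_levels=[reg_codes])
    sR, sP, sI, sE = comps.sum(axis=0)
    tot = sR + sP + sI + sE
    fis_wc = weir_cockerham(panel)   # f with X males excluded
    return HierarchicalFStats(
        levels=list(hierarchy),
        F_IS=fis_wc.overall["f"],
        F_SR=sP / (sP + sI + sE) if (sP + sI + sE) != 0 else np.nan,
        F_RT=sR / tot if tot != 0 else np.nan,
        F_ST=(sR + sP) / tot if tot != 0 else np.nan,
        F_IT=(sR + sP + sI) / tot if tot != 0 else np.nan,
        components=np.array([sR, sP, sI, sE]),
        per_locus_components=comps)


# --------------------------------------------------------------------------
# permutation tests
# --------------------------------------------------------------------------

def _overall_f_from_calls(calls: np.ndarray, groups: np.ndarray) -> float:
    B = C = 0.0
    n_groups = groups.max() + 1
    for l in range(calls.shape[1]):
        if n_groups >= 2:
            comp = _locus_components(calls[:, l], groups, 3)
            B += comp[1]
            C += comp[2]
        else:
            comp = _single_group_components(calls[:, l])
            B += comp[0]
            C += comp[1]
    return B / (B + C) if (B + C) != 0 else np.nan


def _g_over_loci(calls: np.ndarray, groups: np.ndarray) -> float:
    """G summed over loci on genotype x group contingency tables."""
    g = 0.0
    n_groups = groups.max() + 1
    for l in range(calls.shape[1]):
        codes, scored = genotype_codes(calls[:, l])
        if not scored.any():
            continue
        cc, gg = codes[scored], groups[scored]
        table = np.zeros((cc.max() + 1, n_groups))
        np.add.at(table, (cc, gg), 1)
        g += g_statistic(table)
    return g


def permutation_test(panel: GenotypePanel, scheme: str, n_perm: int = 10000,
                     seed: int = 0, region: str | None = None,
                     ) -> PermutationTestResult:
    """Permutation tests for F-statistics.

    Schemes (statistic in parentheses):

    * ``alleles_within_subsamples`` (f) — H1: homozygote excess; alleles are
      shuffled among individuals within each subsample.
    * ``individuals_among_subsamples`` (G) — differentiation among all
      subsamples.
    * ``individuals_within_region`` (G) — differentiation among the
      subsamples of one region (pass ``region=``).
    * ``subsamples_between_regions`` (G) — regional differentiation; whole
      subsamples are reassigned to regions.
    """
    if n_perm < 1:
        raise ValueError("n_perm >= 1 required")
    rng = np.random.default_rng(seed)
    groups, pop_names = _pop_codes(panel)

    if scheme == "alleles_within_subsamples":
        view = panel.fis_view()
        observed = _overall_f_from_calls(view.calls, groups)
        null = _null_f_distribution(view.calls, groups, n_perm, rng)
        stat = "f"
    elif scheme == "individuals_among_subsamples":
        view = panel.diff_view()
        observed = _g_over_loci(view.calls, groups)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _g_over_loci(view.calls, rng.permutation(groups))
        stat = "G"
    elif scheme == "individuals_within_region":
        if region is None:
            raise ValueError("scheme requires region=")
        keep = np.array([i for i, r in
                         enumerate(panel.region_of_individual) if r == region])
        sub = panel.subset(individuals=keep)
        return permutation_test(sub, "individuals_among_subsamples",
                                n_perm=n_perm, seed=seed)
    elif scheme == "subsamples_between_regions":
        view = panel.diff_view()
        regs = panel.region_of_individual
        region_names = sorted(set(regs))
        if len(region_names) < 2:
            raise ValueError("need >= 2 regions")
        pop_region = np.array(
            [region_names.index(panel.regions[p]) for p in pop_names])
        counts = np.bincount(pop_region, minlength=len(region_names))
        if (counts < 2).any() and len(pop_names) < 3:
            raise ValueError("permutation space degenerate: "
                             "too few subsamples per region")
        reg_of_ind = pop_region[groups]
        observed = _g_over_loci(view.calls, reg_of_ind)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(pop_region)
            null[b] = _g_over_loci(view.calls, perm[groups])
        stat = "G"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    p = (np.sum(null >= observed) + 1) / (n_perm + 1)
    return PermutationTestResult(observed=float(observed), statistic=stat,
                                 scheme=scheme, n_perm=n_perm, seed=seed,
                                 p_value=float(p), null_values=null)


def _null_f_distribution(calls: np.ndarray, groups: np.ndarray,
                         n_perm: int, rng) -> np.ndarray:
    """Vectorized null f: reshuffle alleles into pairs within subsamples.

    Within one subsample the summed components depend on the permuted pairing
    only through per-allele dosage sums of squares, so each permutation is a
    cheap bincount-free computation on shuffled allele vectors.
    """
    n, L = calls.shape[0], calls.shape[1]
    n_groups = groups.max() + 1
    # accumulate components per permutation
    B = np.zeros(n_perm)
    C = np.zeros(n_perm)
    for l in range(L):
        a, b = calls[:, l, 0], calls[:, l, 1]
        scored = (a > 0) & (b > 0)
        for g in range(n_groups):
            m = scored & (groups == g)
            k = int(m.sum())
            if k < 2:
                continue
            pool = np.concatenate([a[m], b[m]])
            alleles = np.unique(pool)
            if alleles.size < 2:
                continue
            order = np.argsort(rng.random((n_perm, pool.size)), axis=1)
            shuffled = pool[order]                      # (P, 2k)
            left = shuffled[:, 0::2]
            right = shuffled[:, 1::2]
            # per-allele dosages per permutation
            for al in alleles:
                d = (left == al).astype(np.int64) + (right == al)
                tot = d.sum(axis=1).astype(float)       # constant over perms
                T0 = tot ** 2 / (2 * k)
                Tind = (d.astype(float) ** 2 / 2.0).sum(axis=1)
                Tobs = tot
                sE = (Tobs - Tind) / (2 * k - k)
                sI = (Tind - T0 - (k - 1) * sE) / (2 * k - 2)
                B += sI
                C += sE
    with np.errstate(invalid="ignore", divide="ignore"):
        return B / (B + C)


# --------------------------------------------------------------------------
# confidence intervals
# --------------------------------------------------------------------------

def fstat_confidence_intervals(panel: GenotypePanel, statistic: str = "theta",
                               n_boot: int = 1000, seed: int = 0,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Per-locus jackknife-over-populations CIs and an overall
    bootstrap-over-loci CI for f or theta.

    Jackknife CIs use the normal approximation on pseudovalues; the overall
    CI is a percentile bootstrap of the component-ratio statistic.
    """
    if statistic not in ("f", "theta"):
        raise ValueError("statistic must be 'f' or 'theta'")
    pops = panel.population_names
    rng = np.random.default_rng(seed)
    wc_all = weir_cockerham(panel)

    rows = []
    if len(pops) >= 3:
        for l, locus in enumerate(panel.loci):
            full = wc_all.per_locus[statistic].iloc[l]
            pseudo = []
            for drop in pops:
                keep = np.array([i for i, p in enumerate(panel.populations)
                                 if p != drop])
                sub = panel.subset(individuals=keep)
                est = weir_cockerham(sub).per_locus[statistic].iloc[l]
                pseudo.append(len(pops) * full - (len(pops) - 1) * est)
            pseudo = np.asarray(pseudo, dtype=float)
            if np.isnan(pseudo).any() or np.isnan(full):
                rows.append((locus, full, np.nan, np.nan))
                continue
            se = pseudo.std(ddof=1) / np.sqrt(len(pops))
            z = stats.norm.ppf(1 - alpha / 2)
            rows.append((locus, full, pseudo.mean() - z * se,
                         pseudo.mean() + z * se))
    else:
        for l, locus in enumerate(panel.loci):
            rows.append((locus, wc_all.per_locus[statistic].iloc[l],
                         np.nan, np.nan))

    # overall: percentile bootstrap over loci
    comps_d = wc_all.components_diff
    comps_f = wc_all.components_fis
    L = panel.n_loci
    overall = wc_all.overall[statistic]
    if L >= 2 and n_boot >= 2:
        boots = np.empty(n_boot)
        for i in range(n_boot):
            pick = rng.integers(0, L, size=L)
            if statistic == "theta":
                A, B, C = comps_d[pick].sum(axis=0)
                tot = A + B + C
                boots[i] = A / tot if tot != 0 else np.nan
            else:
                B, C = comps_f[pick].sum(axis=0)
                boots[i] = B / (B + C) if (B + C) != 0 else np.nan
        lo, hi = np.nanpercentile(boots, [100 * alpha / 2,
                                          100 * (1 - alpha / 2)])
    else:
        lo = hi = np.nan
    rows.append(("All", overall, lo, hi))
    return pd.DataFrame(rows, columns=["locus", statistic, "ci_low",
                                       "ci_high"]).set_index("locus")


# --------------------------------------------------------------------------
# gene diversity
# --------------------------------------------------------------------------

def nei_gene_diversity(panel: GenotypePanel) -> pd.DataFrame:
    """Nei's unbiased gene diversity Hs per locus per population.

    Hemizygous male genes at X-linked loci count once. Returns a loci x
    populations frame (NaN where a locus is unscored in a population).
    """
    pops = panel.population_names
    out = np.full((panel.n_loci, len(pops)), np.nan)
    for pi, pop in enumerate(pops):
        idx = panel.individuals_in(pop)
        for l in range(panel.n_loci):
            counts = panel.allele_counts(l, individuals=idx)
            n = sum(counts.values())
            if n < 2:
                continue
            p = np.array(list(counts.values()), dtype=float) / n
            out[l, pi] = n / (n - 1) * (1.0 - (p ** 2).sum())
    return pd.DataFrame(out, index=panel.loci, columns=pops)


def compare_region_diversity(table: pd.DataFrame, panel: GenotypePanel,
                             region_a: str, region_b: str) -> dict:
    """Two-sided Wilcoxon signed-rank on region-mean Hs, paired by locus."""
    pops_a = [p for p in table.columns if panel.regions[p] == region_a]
    pops_b = [p for p in table.columns if panel.regions[p] == region_b]
    if not pops_a or not pops_b:
        raise ValueError("empty region")
    mean_a = table[pops_a].mean(axis=1)
    mean_b = table[pops_b].mean(axis=1)
    d = (mean_a - mean_b).dropna().to_numpy()
    if len(d) == 0 or np.allclose(d, 0):
        return {"statistic": 0.0, "p_value": 1.0,
                "mean_a": float(np.nanmean(mean_a)),
                "mean_b": float(np.nanmean(mean_b))}
    method = "exact" if (len(d) <= 25 and
                         len(np.unique(np.abs(d[d != 0]))) == len(d[d != 0])) \
        else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "mean_a": float(np.nanmean(mean_a)),
            "mean_b": float(np.nanmean(mean_b))}
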