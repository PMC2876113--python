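"""Effective population size by two single-sample methods.

* the linkage-disequilibrium method: Burrows' composite digenic
  disequilibrium between unlinked loci, converted to a squared allelic
  correlation and inverted through Hill's drift expectation
  E[r^2] ~ 1/S + 1/(3 Ne) (the NeEstimator lineage), giving
  Ne = 1 / (3 (rbar^2 - 1/S~)) with S~ the harmonic mean of the
  pairwise-complete sample sizes;
* the heterozygote-excess method for dioecious populations,
  Ne = 1/(-2 F_IS) - F_IS/(1 + F_IS), applicable only where the
  Weir-Cockerham f is negative.

Males are coded homozygous at X-linked loci for the composite LD measure.
No mating-system correction factor is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .panels import GenotypePanel
from .fstats import weir_cockerham

__all__ = ["NeEstimate", "burrows_composite", "ld_ne", "het_excess_ne",
           "balloux_ne"]


@dataclass
class NeEstimate:
    population: str
    method: str                       # ld_burrows | het_excess
    ne: float                         # may be +inf
    r2_mean: float | None = None
    harmonic_s: float | None = None
    f_is: float | None = None
    applicable: bool = True
    detail: dict = field(default_factory=dict)


def burrows_composite(calls_a: np.ndarray, calls_b: np.ndarray) -> dict:
    """Burrows' composite disequilibrium for one locus pair in one sample.

    ``calls_a``/``calls_b`` are ``(n, 2)`` diploid call slices (0 = missing;
    hemizygotes must already be coded homozygous). Returns per-allele-pair
    Delta and r plus the pair mean r^2; the r denominator uses Weir's
    Hardy-Weinberg-departure-corrected variances, which bounds |r| by 1 at
    full coupling.
    """
    scored = (calls_a[:, 0] > 0) & (calls_b[:, 0] > 0) \
        & (calls_a[:, 1] > 0) & (calls_b[:, 1] > 0)
    n = int(scored.sum())
    if n < 2:
        return {"n": n, "pairs": [], "r2_mean": np.nan, "skipped":
                "fewer than 2 complete individuals"}
    A = calls_a[scored]
    B = calls_b[scored]
    alleles_a = np.unique(A)
    alleles_b = np.unique(B)
    if alleles_a.size < 2 or alleles_b.size < 2:
        return {"n": n, "pairs": [], "r2_mean": np.nan,
                "skipped": "monomorphic locus in pair"}
    pairs = []
    r2s = []
    for al in alleles_a:
        da = (A == al).sum(axis=1)                   # dosage 0/1/2
        p = da.sum() / (2 * n)
        hom_a = (da == 2).mean()
        Da = hom_a - p ** 2                          # HW departure
        for bl in alleles_b:
            db = (B == bl).sum(axis=1)
            q = db.sum() / (2 * n)
            hom_b = (db == 2).mean()
            Db = hom_b - q ** 2
            delta = (da * db).sum() / (2.0 * n) - 2.0 * p * q
            denom = (p * (1 - p) + Da) * (q * (1 - q) + Db)
            r = delta / np.sqrt(denom) if denom > 0 else np.nan
            pairs.append({"allele_a": int(al), "allele_b": int(bl),
                          "delta": float(delta), "r": float(r)})
            if np.isfinite(r):
                r2s.append(r ** 2)
    r2_mean = float(np.mean(r2s)) if r2s else np.nan
    return {"n": n, "pairs": pairs, "r2_mean": r2_mean}


def ld_ne(panel: GenotypePanel, population: str,
          exclude_loci: list[str] | None = None) -> NeEstimate:
    """LD effective size for one population.

    r^2 is averaged over allele pairs within each locus pair, then
    arithmetically over locus pairs; S~ is the harmonic mean of
    pairwise-complete sample sizes. rbar^2 <= 1/S~ reports an infinite
    estimate (drift signal indistinguishable from sampling noise).
    """
    idx = panel.individuals_in(population)
    view = panel.diff_view()
    loci = [l for l in panel.loci
            if not exclude_loci or l not in set(exclude_loci)]
    li = [panel.loci.index(l) for l in loci]
    per_pair = []
    sizes = []
    for a, b in combinations(range(len(li)), 2):
        res = burrows_composite(view.calls[idx][:, li[a]],
                                view.calls[idx][:, li[b]])
        if res["pairs"]:
            per_pair.append(res["r2_mean"])
            sizes.append(res["n"])
    if len(per_pair) < 1:
        return NeEstimate(population, "ld_burrows", np.nan,
                          applicable=False,
                          detail={"reason": "fewer than 2 informative loci"})
    r2 = float(np.mean(per_pair))
    s_tilde = len(sizes) / np.sum(1.0 / np.asarray(sizes, dtype=float))
    excess = r2 - 1.0 / s_tilde
    ne = float("inf") if excess <= 0 else 1.0 / (3.0 * excess)
    return NeEstimate(population, "ld_burrows", ne, r2_mean=r2,
                      harmonic_s=float(s_tilde),
                      detail={"n_locus_pairs": len(per_pair)})


def balloux_ne(f_is: float) -> float:
    """Ne = 1/(-2 F_IS) - F_IS/(1 + F_IS), defined for F_IS < 0 only."""
    if not np.isfinite(f_is) or f_is >= 0:
        raise ValueError("heterozygote-excess Ne needs F_IS < 0")
    if f_is <= -1.0:
        return float("inf")
    return 1.0 / (-2.0 * f_is) - f_is / (1.0 + f_is)


def het_excess_ne(panel: GenotypePanel, population: str,
                  exclude_loci: list[str] | None = None) -> NeEstimate:
    """Heterozygote-excess Ne = 1/(-2 f) - f/(1 + f); needs f < 0."""
    idx = panel.individuals_in(population)
    sub = panel.subset(individuals=idx)
    if exclude_loci:
        sub = sub.drop_loci(exclude_loci)
    f = weir_cockerham(sub).overall["f"]
    if not np.isfinite(f) or f >= 0:
        return NeEstimate(population, "het_excess", np.nan, f_is=f,
                          applicable=False,
                          detail={"reason": "no heterozygote excess (f >= 0)"})
    return NeEstimate(population, "het_excess", float(balloux_ne(f)),
                      f_is=float(f))
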