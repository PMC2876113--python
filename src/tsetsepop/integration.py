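"""Mantel tests between marker distance matrices and the pipeline driver.

The Mantel statistic is the Pearson correlation of the off-diagonal
upper-triangle entries of two labelled distance matrices; the null is built
by simultaneous row/column permutation of the second matrix, and the test is
one-sided toward positive association (concordance among markers).

:func:`run_pipeline` executes the full study emulation or file-backed
analysis: simulate/load -> locus QC -> F-statistics -> effective sizes ->
bottleneck -> chord distances + NJ tree -> mtDNA statistics -> morphometrics
-> Mantel integration, writing plain-text tables, Newick and a JSON summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .bottleneck import bottleneck_test, detection_window
from .diagnostics import (expected_blanks_test, holm_correction,
                          ld_pairwise_tests, null_allele_table,
                          significant_count_binomial)
from .fstats import (compare_region_diversity, fstat_confidence_intervals,
                     hierarchical_fstats, nei_gene_diversity,
                     permutation_test, weir_cockerham)
from .morpho import gpa, mahalanobis_cva, partial_warps
from .mtdna import (collapse_haplotypes, hudson_differentiation,
                    parsimony_network, sequence_diversity)
from .ne import het_excess_ne, ld_ne
from .panels import DistanceMatrix
from .simulate import (SimConfig, simulate_coi_panel, simulate_landmarks,
                       simulate_microsat_panel, study_config)
from .tree import chord_distance_matrix, neighbor_joining, to_newick

__all__ = ["MantelResult", "mantel", "run_pipeline"]


@dataclass
class MantelResult:
    pair: tuple[str, str]
    r: float
    r_squared: float
    n_perm: int
    seed: int
    p_value: float


def mantel(mat_a: DistanceMatrix, mat_b: DistanceMatrix,
           n_perm: int = 10000, seed: int = 0) -> MantelResult:
    """One-sided Mantel test (H1: positive association)."""
    if set(mat_a.labels) != set(mat_b.labels):
        raise ValueError("matrices must share labels")
    if len(mat_a.labels) < 4:
        raise ValueError("need >= 4 labels")
    b = mat_b.reorder(mat_a.labels)
    va = mat_a.condensed()
    vb = b.condensed()
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero-variance distance matrix: r undefined")
    r = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    m = len(mat_a.labels)
    iu = np.triu_indices(m, 1)
    B = b.values
    cnt = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        vb_p = B[np.ix_(perm, perm)][iu]
        if np.corrcoef(va, vb_p)[0, 1] >= r:
            cnt += 1
    p = (cnt + 1) / (n_perm + 1)
    return MantelResult(pair=(mat_a.statistic, mat_b.statistic), r=r,
                        r_squared=r * r, n_perm=n_perm, seed=seed,
                        p_value=float(p))


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: SimConfig | str | None = None, out_dir="report",
                 seed: int = 0, n_perm: int = 2000,
                 n_perm_morpho: int = 500, bottleneck_reps: int = 300,
                 bottleneck_models: tuple[str, ...] = ("IAM", "TPM", "SMM"),
                 exclude_loci: list[str] | None = None) -> dict:
    """Run every analysis stage on a simulated study and write the report.

    Returns the JSON-serializable summary (also written to
    ``<out_dir>/summary.json``). Stage failures are recorded in the summary
    under ``failures`` rather than aborting later stages.
    """
    if config is None:
        config = study_config(seed)
    elif isinstance(config, (str, Path)):
        config = SimConfig.from_json(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in ss.spawn(16)]
    summary: dict = {"seed": seed, "config_seed": config.seed,
                     "failures": {}, "stages": {}}

    panel = simulate_microsat_panel(config, seed=seeds[0])
    pio.write_genotypes(panel, out / "genotypes.genepop", "genepop")
    summary["stages"]["simulate"] = {
        "n_individuals": panel.n_individuals, "n_loci": panel.n_loci,
        "populations": panel.population_names}

    def stage(name, fn):
        try:
            summary["stages"][name] = fn()
        except Exception as exc:   # recorded, not fatal
            summary["failures"][name] = f"{type(exc).__name__}: {exc}"

    # -- locus QC -------------------------------------------------------
    def qc():
        est = null_allele_table(panel)
        blanks = expected_blanks_test(panel, est)
        ld, dropped = ld_pairwise_tests(panel, n_perm=n_perm, seed=seeds[1])
        n_sig = sum(1 for t in ld if t.p_value <= 0.05)
        multi_p = significant_count_binomial(n_sig, len(ld)) if ld else 1.0
        pd.DataFrame([vars(e) for e in est]).to_csv(
            out / "qc_null_alleles.tsv", sep="\t", index=False)
        pd.DataFrame([vars(t) for t in ld]).to_csv(
            out / "qc_ld_pairs.tsv", sep="\t", index=False)
        return {"blanks_test": blanks,
                "ld_pairs": len(ld), "ld_significant": n_sig,
                "ld_multitest_p": multi_p,
                "ld_excluded": dropped}
    stage("qc", qc)

    work = panel.drop_loci(exclude_loci) if exclude_loci else panel

    # -- F-statistics ---------------------------------------------------
    def fstats_stage():
        wc = weir_cockerham(work)
        hier = hierarchical_fstats(work)
        ci_f = fstat_confidence_intervals(work, "f", seed=seeds[2])
        ci_t = fstat_confidence_intervals(work, "theta", seed=seeds[3])
        p_fis = permutation_test(work, "alleles_within_subsamples",
                                 n_perm=n_perm, seed=seeds[4]).p_value
        p_fst = permutation_test(work, "individuals_among_subsamples",
                                 n_perm=n_perm, seed=seeds[5]).p_value
        regions = sorted(set(work.region_of_individual))
        p_fsr = p_frt = None
        multi_pop_regions = [r for r in regions if len(
            {p for p in work.population_names if work.regions[p] == r}) >= 2]
        if multi_pop_regions:
            p_fsr = permutation_test(work, "individuals_within_region",
                                     region=multi_pop_regions[0],
                                     n_perm=n_perm, seed=seeds[6]).p_value
        if len(regions) == 2:
            p_frt = permutation_test(work, "subsamples_between_regions",
                                     n_perm=n_perm, seed=seeds[7]).p_value
        wc.per_locus.to_csv(out / "fstats_per_locus.tsv", sep="\t")
        ci_f.to_csv(out / "fis_ci.tsv", sep="\t")
        ci_t.to_csv(out / "theta_ci.tsv", sep="\t")
        div = nei_gene_diversity(work)
        div.to_csv(out / "gene_diversity.tsv", sep="\t")
        region_cmp = None
        if len(regions) == 2:
            region_cmp = compare_region_diversity(div, work, regions[0],
                                                  regions[1])
        return {"overall": wc.overall,
                "hierarchical": {"F_IS": hier.F_IS, "F_SR": hier.F_SR,
                                 "F_RT": hier.F_RT, "F_ST": hier.F_ST},
                "p_fis": p_fis, "p_fst": p_fst, "p_fsr": p_fsr,
                "p_frt": p_frt, "region_diversity": region_cmp}
    stage("fstats", fstats_stage)

    # -- effective sizes ------------------------------------------------
    def ne_stage():
        rows = []
        for pop in work.population_names:
            for fn in (ld_ne, het_excess_ne):
                est = fn(work, pop)
                rows.append({"population": pop, "method": est.method,
                             "ne": est.ne, "r2": est.r2_mean,
                             "harmonic_s": est.harmonic_s, "f_is": est.f_is,
                             "applicable": est.applicable})
        pd.DataFrame(rows).to_csv(out / "ne_estimates.tsv", sep="\t",
                                  index=False)
        return {"estimates": [
            {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
             for k, v in r.items()} for r in rows]}
    stage("ne", ne_stage)

    # -- bottleneck -----------------------------------------------------
    def bottleneck_stage():
        rows = []
        for pop in work.population_names:
            for model in bottleneck_models:
                try:
                    res = bottleneck_test(work, pop, model=model,
                                          n_reps=bottleneck_reps,
                                          seed=seeds[8])
                    rows.append({"population": pop, "model": model,
                                 "p_value": res.p_value})
                except Exception as exc:
                    rows.append({"population": pop, "model": model,
                                 "p_value": None, "note": str(exc)})
        pd.DataFrame(rows).to_csv(out / "bottleneck.tsv", sep="\t",
                                  index=False)
        window = None
        if config.bottleneck is not None:
            w = detection_window(config.bottleneck[1])
            window = {"ne_pb": w.ne_pb, "lower": w.lower, "upper": w.upper}
        return {"tests": rows, "window": window}
    stage("bottleneck", bottleneck_stage)

    # -- chord distances and NJ tree -------------------------------------
    chord = None

    def tree_stage():
        nonlocal chord
        chord = chord_distance_matrix(work)
        pio.write_distance_matrix(chord, out / "chord_distances.phylip")
        tree = neighbor_joining(chord)
        (out / "nj_tree.nwk").write_text(to_newick(tree) + "\n")
        return {"newick": to_newick(tree),
                "clamped_branches": tree.clamped_branches}
    stage("tree", tree_stage)

    # -- mtDNA ----------------------------------------------------------
    kst = None

    def mtdna_stage():
        nonlocal kst
        seqs = simulate_coi_panel(config, seed=seeds[9])
        pio.write_alignment(seqs, out / "coi.fasta")
        pops = seqs.population_names
        div_rows = []
        for pop in pops + [None]:
            st = sequence_diversity(seqs, pop)
            div_rows.append({"population": pop or "Total", "n": st.n,
                             "haplotypes": st.n_haplotypes, "S": st.s,
                             "Hd": st.hd, "Hd_var": st.hd_variance,
                             "Pi": st.pi, "K": st.k,
                             "K_var": st.k_total_variance})
        pd.DataFrame(div_rows).to_csv(out / "mtdna_diversity.tsv", sep="\t",
                                      index=False)
        m = len(pops)
        kst_vals = np.zeros((m, m))
        diff_rows = []
        rng = np.random.default_rng(seeds[10])
        for i in range(m):
            for j in range(i + 1, m):
                d = hudson_differentiation(seqs, pops[i], pops[j],
                                           n_perm=n_perm,
                                           seed=int(rng.integers(2 ** 31)))
                kst_vals[i, j] = kst_vals[j, i] = max(d.kst_star, 0.0)
                diff_rows.append({"pop_a": pops[i], "pop_b": pops[j],
                                  "fst": d.fst, "hst": d.hst,
                                  "kst_star": d.kst_star,
                                  "p_hst": d.p_hst, "p_kst": d.p_kst})
        pd.DataFrame(diff_rows).to_csv(out / "mtdna_differentiation.tsv",
                                       sep="\t", index=False)
        reject, adjusted = holm_correction([r["p_kst"] for r in diff_rows])
        table = collapse_haplotypes(seqs)
        net = parsimony_network(table, connection_limit=11)
        pd.DataFrame(net.edges, columns=["from", "to", "steps"]).to_csv(
            out / "haplotype_network.tsv", sep="\t", index=False)
        kst = DistanceMatrix(pops, kst_vals, statistic="kst")
        return {"n_haplotypes": table.n_haplotypes,
                "kst_significant_after_holm": int(reject.sum()),
                "network_components": len(net.components)}
    stage("mtdna", mtdna_stage)

    # -- morphometrics ---------------------------------------------------
    dm_morpho = None

    def morpho_stage():
        nonlocal dm_morpho
        if not config.landmark_groups:
            raise ValueError("no landmark block in config")
        lm = simulate_landmarks(config, seed=seeds[11])
        pio.write_landmarks(lm, out / "wings.tps")
        proc = gpa(lm)
        shape = partial_warps(proc)
        cva = mahalanobis_cva(shape, lm.groups, n_perm=n_perm_morpho,
                              seed=seeds[12])
        dm_morpho = cva.d_matrix
        pio.write_distance_matrix(dm_morpho, out / "mahalanobis.phylip")
        rows = [{"group": g, "correct": c, "total": t,
                 "percent": 100.0 * c / t}
                for g, (c, t) in cva.reclassified.items()]
        pd.DataFrame(rows).to_csv(out / "reclassification.tsv", sep="\t",
                                  index=False)
        return {"n_shape_variables": shape.scores.shape[1],
                "reclassification": rows}
    stage("morpho", morpho_stage)

    # -- Mantel integration ----------------------------------------------
    def mantel_stage():
        mats = {"chord": chord, "kst": kst, "mahalanobis": dm_morpho}
        avail = {k: v for k, v in mats.items() if v is not None}
        rows = []
        rng = np.random.default_rng(seeds[13])
        keys = list(avail)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                res = mantel(avail[keys[i]], avail[keys[j]], n_perm=n_perm,
                             seed=int(rng.integers(2 ** 31)))
                rows.append({"pair": f"{keys[i]}~{keys[j]}", "r": res.r,
                             "r_squared": res.r_squared,
                             "p_value": res.p_value})
        pd.DataFrame(rows).to_csv(out / "mantel.tsv", sep="\t", index=False)
        return {"tests": rows, "skipped": [k for k in mats if k not in avail]}
    stage("mantel", mantel_stage)

    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 default=str))
    return summary
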