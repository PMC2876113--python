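"""F-statistic estimators against independent textbook evaluations, plus the
permutation and diversity machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsetsepop.fstats import (compare_region_diversity,
                              fstat_confidence_intervals, hierarchical_fstats,
                              nei_gene_diversity, permutation_test,
                              weir_cockerham)
from tsetsepop.simulate import simulate_microsat_panel

from conftest import make_panel


def wc84_reference(calls, groups):
    """Independent evaluation of the Weir-Cockerham (1984) a/b/c component
    formulas (unequal sample sizes, multiallelic), used as the oracle."""
    calls = np.asarray(calls)
    groups = np.asarray(groups)
    r = groups.max() + 1
    alleles = np.unique(calls[calls > 0])
    comps = []
    n_i = np.array([(groups == g).sum() for g in range(r)], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    for al in alleles:
        dos = (calls == al).sum(axis=1)
        p_i = np.array([dos[groups == g].sum() / (2 * n_i[g])
                        for g in range(r)])
        h_i = np.array([(dos[groups == g] == 1).mean() for g in range(r)])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                               - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        comps.append((a, b, c))
    return np.asarray(comps).sum(axis=0)


class TestWeirCockerham:
    def test_all_homozygotes_give_f_one(self):
        panel = make_panel([[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]],
                           ["p"] * 4)
        assert weir_cockerham(panel).overall["f"] == pytest.approx(1.0)

    def test_fixed_populations_match_brute_force(self):
        calls = [[(1, 1)]] * 20 + [[(2, 2)]] * 20
        panel = make_panel(calls, ["a"] * 20 + ["b"] * 20)
        wc = weir_cockerham(panel)
        a, b, c = wc84_reference(panel.calls[:, 0, :],
                                 np.repeat([0, 1], 20))
        assert wc.overall["theta"] == pytest.approx(a / (a + b + c),
                                                    abs=1e-12)
        assert wc.overall["theta"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_components_equal_wc84_oracle(self, seed):
        # <= 3 populations x <= 2 loci x <= 6 individuals each
        rng = np.random.default_rng(seed)
        r = rng.integers(2, 4)
        sizes = rng.integers(3, 7, size=r)
        groups = np.repeat(np.arange(r), sizes)
        pops = [f"p{g}" for g in groups]
        L = rng.integers(1, 3)
        calls = np.sort(rng.integers(1, 5, size=(groups.size, L, 2)), axis=2)
        panel = make_panel(calls, pops)
        wc = weir_cockerham(panel)
        for l in range(L):
            ref = wc84_reference(calls[:, l, :], groups)
            assert np.allclose(wc.components_diff[l], ref, atol=1e-12)

    def test_panmictic_simulation_gives_small_f(self, flat_config):
        fs = [weir_cockerham(simulate_microsat_panel(flat_config, seed=s)
                             ).overall["f"] for s in range(10)]
        assert abs(np.mean(fs)) < 0.05

    def test_order_invariance(self, study_panel):
        base = weir_cockerham(study_panel).overall
        perm = np.random.default_rng(0).permutation(
            study_panel.n_individuals)
        shuffled = study_panel.subset(individuals=perm)
        loci_perm = list(reversed(study_panel.loci))
        shuffled = shuffled.subset(loci=loci_perm)
        again = weir_cockerham(shuffled).overall
        for key in ("f", "theta", "F"):
            assert again[key] == pytest.approx(base[key], abs=1e-12)

    def test_monomorphic_locus_contributes_nothing(self):
        calls = [[(1, 2), (5, 5)], [(1, 1), (5, 5)], [(2, 2), (5, 5)],
                 [(1, 2), (5, 5)]]
        panel = make_panel(calls, ["a", "a", "b", "b"])
        wc = weir_cockerham(panel)
        assert np.isnan(wc.per_locus["theta"].iloc[1])
        assert (wc.components_diff[1] == 0).all()


class TestHierarchical:
    def test_duplicated_regions_have_zero_frt(self):
        rng = np.random.default_rng(1)
        calls = np.sort(rng.integers(1, 6, size=(20, 3, 2)), axis=2)
        calls = np.concatenate([calls, calls])          # mirror individuals
        pops = (["a"] * 10 + ["b"] * 10) * 2
        pops = ["a"] * 10 + ["b"] * 10 + ["a2"] * 10 + ["b2"] * 10
        regions = {"a": "R1", "b": "R1", "a2": "R2", "b2": "R2"}
        panel = make_panel(calls, pops, regions=regions)
        h = hierarchical_fstats(panel)
        assert abs(h.F_RT) < 0.03

    def test_single_region_collapses_to_two_level_theta(self, study_panel):
        keep = [i for i, r in enumerate(study_panel.region_of_individual)
                if r == "Niayes"]
        sub = study_panel.subset(individuals=np.array(keep))
        h = hierarchical_fstats(sub)
        wc = weir_cockerham(sub)
        assert h.F_ST == pytest.approx(wc.overall["theta"], abs=1e-10)
        assert h.F_IS == pytest.approx(wc.overall["f"], abs=1e-10)

    def test_statistics_within_bounds(self, study_panel):
        h = hierarchical_fstats(study_panel)
        for v in (h.F_IS, h.F_SR, h.F_RT, h.F_ST, h.F_IT):
            assert -1.0 <= v <= 1.0


class TestPermutationTests:
    def test_fixed_difference_populations_maximal_g(self):
        calls = [[(1, 1)]] * 15 + [[(2, 2)]] * 15
        panel = make_panel(calls, ["a"] * 15 + ["b"] * 15)
        res = permutation_test(panel, "individuals_among_subsamples",
                               n_perm=99, seed=3)
        assert res.p_value == pytest.approx(1 / 100)

    def test_determinism(self, study_panel):
        a = permutation_test(study_panel, "alleles_within_subsamples",
                             n_perm=200, seed=42)
        b = permutation_test(study_panel, "alleles_within_subsamples",
                             n_perm=200, seed=42)
        assert a.p_value == b.p_value

    def test_observed_f_matches_estimator(self, study_panel):
        res = permutation_test(study_panel, "alleles_within_subsamples",
                               n_perm=5, seed=0)
        wc = weir_cockerham(study_panel)
        assert res.observed == pytest.approx(wc.overall["f"], abs=1e-12)

    def test_region_schemes_run(self, study_panel):
        res = permutation_test(study_panel, "individuals_within_region",
                               region="Niayes", n_perm=99, seed=1)
        assert 0 < res.p_value <= 1
        res2 = permutation_test(study_panel, "subsamples_between_regions",
                                n_perm=99, seed=1)
        assert 0 < res2.p_value <= 1

    def test_degenerate_region_permutation_rejected(self):
        calls = [[(1, 2)], [(1, 1)], [(2, 2)], [(1, 2)]]
        panel = make_panel(calls, ["a", "a", "b", "b"],
                           regions={"a": "R1", "b": "R2"})
        with pytest.raises(ValueError, match="degenerate"):
            permutation_test(panel, "subsamples_between_regions", n_perm=9,
                             seed=0)


class TestConfidenceIntervals:
    def test_identical_populations_zero_width_jackknife(self):
        rng = np.random.default_rng(3)
        block = np.sort(rng.integers(1, 5, size=(8, 2, 2)), axis=2)
        calls = np.concatenate([block, block, block])
        pops = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        panel = make_panel(calls, pops)
        ci = fstat_confidence_intervals(panel, "theta", n_boot=50, seed=0)
        per_locus = ci.drop(index="All").dropna()
        widths = per_locus["ci_high"] - per_locus["ci_low"]
        assert np.allclose(widths, 0.0, atol=1e-12)

    def test_degenerate_bootstrap_flagged(self, study_panel):
        ci = fstat_confidence_intervals(study_panel, "theta", n_boot=1,
                                        seed=0)
        assert np.isnan(ci.loc["All", "ci_low"])

    def test_bootstrap_covers_generator_target(self, study_panel):
        ci = fstat_confidence_intervals(study_panel, "theta", n_boot=300,
                                        seed=1)
        lo, hi = ci.loc["All", "ci_low"], ci.loc["All", "ci_high"]
        assert lo < ci.loc["All", "theta"] < hi


class TestDiversity:
    def test_monomorphic_locus_has_zero_hs(self):
        panel = make_panel([[(5, 5)], [(5, 5)], [(5, 5)]], ["p"] * 3)
        table = nei_gene_diversity(panel)
        assert table.iloc[0, 0] == 0.0

    def test_uniformly_more_diverse_region_exact_wilcoxon(self):
        # 10 loci, region A more diverse at all: two-sided exact P = 2/2^10
        loci = [f"L{i}" for i in range(10)]
        table = pd.DataFrame({"a": np.linspace(0.5, 0.8, 10),
                              "b": np.linspace(0.3, 0.55, 10)}, index=loci)
        panel = make_panel([[(1, 2)] * 10, [(1, 1)] * 10],
                           ["a", "b"], regions={"a": "A", "b": "B"},
                           loci=loci)
        res = compare_region_diversity(table, panel, "A", "B")
        assert res["p_value"] == pytest.approx(2 / 2 ** 10)

    def test_identical_regions_give_p_one(self):
        loci = [f"L{i}" for i in range(6)]
        vals = np.linspace(0.2, 0.7, 6)
        table = pd.DataFrame({"a": vals, "b": vals}, index=loci)
        panel = make_panel([[(1, 2)] * 6, [(1, 1)] * 6], ["a", "b"],
                           regions={"a": "A", "b": "B"}, loci=loci)
        res = compare_region_diversity(table, panel, "A", "B")
        assert res["p_value"] == 1.0

    def test_x_linked_gene_counts_single_count_males(self):
        # one female het + one male hemizygote: 3 genes, alleles 1,2,3
        panel = make_panel([[(1, 2)], [(3, 0)]], ["p", "p"],
                           sex=["F", "M"], x_linked=[True], loci=["Xq"])
        counts = panel.allele_counts(0)
        assert counts == {1: 1, 2: 1, 3: 1}
        hs = nei_gene_diversity(panel).iloc[0, 0]
        assert hs == pytest.approx(3 / 2 * (1 - 3 * (1 / 3) ** 2))
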