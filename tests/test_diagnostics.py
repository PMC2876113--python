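"""Null-allele estimation, blank/binomial tests, LD tests and Holm."""

import math

import numpy as np
import pytest

from tsetsepop.diagnostics import (brookfield2_null_frequency,
                                   expected_blanks_test, holm_correction,
                                   ld_pairwise_tests, major_allele_filter,
                                   null_allele_table,
                                   significant_count_binomial)
from tsetsepop.simulate import (LocusSpec, PopulationSpec, SimConfig,
                                simulate_microsat_panel)

from conftest import make_panel


def deficit_panel(n_het, n_hom, n_blank):
    """Single-locus panel with fixed class counts and He' = 0.5."""
    calls = [[(1, 2)]] * n_het
    calls += [[(1, 1)]] * (n_hom // 2) + [[(2, 2)]] * (n_hom - n_hom // 2)
    calls += [[(0, 0)]] * n_blank
    return make_panel(calls, ["p"] * (n_het + n_hom + n_blank))


class TestBrookfield:
    def test_no_deficit_no_blanks_gives_zero(self):
        # observed het proportion equals He': no evidence of a null allele
        panel = deficit_panel(10, 10, 0)
        est = brookfield2_null_frequency(panel, 0)
        assert est.p_n == 0.0

    def test_all_blank_gives_one(self):
        panel = make_panel([[(0, 0)], [(0, 0)], [(1, 2)]], ["p"] * 3)
        panel.calls[2] = 0
        est = brookfield2_null_frequency(panel, 0)
        assert est.undefined or est.p_n == 1.0

    def test_monotone_in_het_deficit(self):
        estimates = [brookfield2_null_frequency(
            deficit_panel(h, 20 - h, 4), 0).p_n for h in (10, 8, 6, 4, 2)]
        assert all(a <= b + 1e-9 for a, b in zip(estimates, estimates[1:]))

    def test_recovers_simulated_null_frequency(self):
        pops = [PopulationSpec("P1", "R", 25, 0),
                PopulationSpec("P2", "R", 25, 0)]
        loci = [LocusSpec("L0", null_freq=0.2), LocusSpec("L1")]
        ests, clean = [], []
        for s in range(20):
            cfg = SimConfig(populations=pops, loci=loci, f_sr=0.02,
                            f_rt=0.0, seed=s)
            panel = simulate_microsat_panel(cfg)
            ests.append(brookfield2_null_frequency(panel, "L0").p_n)
            clean.append(brookfield2_null_frequency(panel, "L1").p_n)
        assert 0.1 <= np.mean(ests) <= 0.3
        assert np.mean(clean) < 0.1

    def test_x_linked_uses_females_only(self, study_panel):
        table = null_allele_table(study_panel)
        assert len(table) == study_panel.n_loci
        for est in table:
            assert est.undefined or 0.0 <= est.p_n <= 1.0


class TestBlanksTest:
    def test_closed_form_zero_observed(self):
        # expected blank probability 0.25, n = 20, observed 0: P = 0.75^20
        panel = make_panel([[(1, 2)]] * 20, ["p"] * 20)
        est = brookfield2_null_frequency(panel, 0)
        est.p_n = 0.5                      # forces p_blank = 0.25
        res = expected_blanks_test(panel, [est])
        assert res["p_value"] == pytest.approx(0.75 ** 20, rel=1e-9)

    def test_observed_equal_expected_not_significant(self):
        panel = deficit_panel(8, 8, 4)     # some blanks present
        res = expected_blanks_test(panel, [brookfield2_null_frequency(panel, 0)])
        assert res["p_value"] > 0.3

    def test_no_nulls_no_blanks_p_one(self):
        panel = make_panel([[(1, 2)]] * 10, ["p"] * 10)
        res = expected_blanks_test(panel, [brookfield2_null_frequency(panel, 0)])
        assert res["p_value"] == 1.0


class TestLD:
    def test_duplicated_locus_is_maximal_association(self):
        rng = np.random.default_rng(0)
        geno = np.sort(rng.integers(1, 4, size=(25, 2)), axis=1)
        calls = np.stack([geno, geno], axis=1)
        panel = make_panel(calls, ["p"] * 25)
        res, _ = ld_pairwise_tests(panel, n_perm=99, seed=1)
        assert len(res) == 1
        assert res[0].p_value == pytest.approx(1 / 100)

    def test_major_allele_filter_excludes_locus(self):
        rng = np.random.default_rng(2)
        common = np.ones((40, 2), dtype=int)
        common[:2] = [1, 2]                # major allele at 0.975
        poly = np.sort(rng.integers(1, 5, size=(40, 3, 2)), axis=2)
        calls = np.concatenate([common[:, None, :], poly], axis=1)
        panel = make_panel(calls, ["p"] * 40)
        keep, dropped = major_allele_filter(panel)
        assert [d[0] for d in dropped] == ["L1"]
        res, dropped2 = ld_pairwise_tests(panel, n_perm=9, seed=0)
        assert len(res) == math.comb(3, 2)

    def test_pair_list_invariant_to_locus_order(self, study_panel):
        res_a, _ = ld_pairwise_tests(study_panel.subset(
            loci=study_panel.loci[:4]), n_perm=49, seed=5)
        reordered = study_panel.subset(loci=list(reversed(
            study_panel.loci[:4])))
        res_b, _ = ld_pairwise_tests(reordered, n_perm=49, seed=5)
        assert {(t.locus_a, t.locus_b) for t in res_a} == \
            {(t.locus_a, t.locus_b) for t in res_b}


class TestMultipleTesting:
    def test_binomial_boundaries(self):
        assert significant_count_binomial(0, 36) == 1.0
        assert significant_count_binomial(36, 36) == pytest.approx(0.05 ** 36)

    def test_four_of_thirtysix_matches_enumeration(self):
        # independent enumeration of the exact upper tail
        expect = sum(math.comb(36, k) * 0.05 ** k * 0.95 ** (36 - k)
                     for k in range(4, 37))
        assert significant_count_binomial(4, 36) == pytest.approx(
            expect, rel=1e-12)
        assert round(significant_count_binomial(4, 36), 4) == 0.1037

    def test_holm_study_pattern(self):
        # the bottleneck P-value triple: two rejected, one not
        reject, adjusted = holm_correction([0.001, 0.001, 0.116])
        assert list(reject) == [True, True, False]
        assert adjusted[2] == pytest.approx(0.116)

    def test_holm_single_p_unchanged(self):
        _, adjusted = holm_correction([0.03])
        assert adjusted[0] == pytest.approx(0.03)

    def test_holm_rejects_superset_of_bonferroni(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(8) ** 2
            holm, _ = holm_correction(p)
            bonf = p <= 0.05 / len(p)
            assert (holm | ~bonf).all()

    def test_all_ones_rejects_none(self):
        reject, _ = holm_correction([1.0, 1.0, 1.0])
        assert not reject.any()
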