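"""Sequence diversity/differentiation statistics and the haplotype network."""

import numpy as np
import pytest

from tsetsepop.mtdna import (collapse_haplotypes, haplotype_diversity,
                             hudson_differentiation, pairwise_differences,
                             parsimony_network, sequence_diversity)
from tsetsepop.panels import SequencePanel

from conftest import two_haplotype_panel


def brute_force_k(sequences):
    """Double loop over all sequence pairs (oracle for K)."""
    n = len(sequences)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(sequences[i], sequences[j]))
    return total / (n * (n - 1) / 2)


def seq_panel(seq_by_pop, regions=None):
    ids, pops, seqs = [], [], []
    for pop, sequences in seq_by_pop.items():
        for i, s in enumerate(sequences):
            ids.append(f"{pop}{i}")
            pops.append(pop)
            seqs.append(s)
    regions = regions or {p: p for p in seq_by_pop}
    return SequencePanel(ids=ids, populations=pops, regions=regions,
                         sequences=seqs)


class TestCollapse:
    def test_identical_sequences_one_haplotype(self):
        panel = seq_panel({"DiacsawPeul": ["ACGTACGT"] * 30})
        table = collapse_haplotypes(panel)
        assert table.n_haplotypes == 1
        assert table.segregating_sites == []

    def test_one_difference_two_haplotypes(self):
        panel = seq_panel({"p": ["ACGT", "ACGA"]})
        table = collapse_haplotypes(panel)
        assert table.n_haplotypes == 2
        assert len(table.segregating_sites) == 1

    def test_case_insensitive(self):
        a = collapse_haplotypes(seq_panel({"p": ["acgt", "ACGT", "ACGA"]}))
        assert a.n_haplotypes == 2

    def test_sites_with_n_or_gap_dropped(self):
        panel = seq_panel({"p": ["ACGT", "ACNT", "AC-T"]})
        table = collapse_haplotypes(panel)
        assert table.n_haplotypes == 1   # the ambiguous column is removed


class TestDiversity:
    @pytest.mark.parametrize("counts,expected_hd,expected_var", [
        ((19, 6), 0.380, 8.33e-3),
        ((25, 2), 0.142, 7.43e-3),
        ((30,), 0.000, 0.0),
    ])
    def test_table_worked_haplotype_diversities(self, counts, expected_hd,
                                                expected_var):
        if sum(counts) < 2:
            pytest.skip("needs n >= 2")
        hd, var = haplotype_diversity(counts)
        assert round(hd, 3) == expected_hd
        assert var == pytest.approx(expected_var, abs=5e-4)

    def test_pout_configuration_k_and_pi(self):
        panel = two_haplotype_panel(19, 6, length=738)
        pw = pairwise_differences(panel)
        assert pw["k"] == pytest.approx(114 / 300)
        assert pw["pi"] == pytest.approx(0.38 / 738, rel=1e-6)
        assert round(pw["pi"], 5) == 0.00051

    def test_k_equals_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        seqs = ["".join(rng.choice(list(bases), 40)) for _ in range(12)]
        panel = seq_panel({"p": seqs})
        pw = pairwise_differences(panel)
        assert pw["k"] == pytest.approx(brute_force_k(panel.sequences),
                                        abs=1e-12)

    def test_pi_times_length_equals_k(self):
        panel = two_haplotype_panel(10, 5, length=100)
        pw = pairwise_differences(panel)
        assert pw["pi"] * pw["length"] == pytest.approx(pw["k"], abs=1e-12)

    def test_hd_label_invariance(self):
        assert haplotype_diversity([5, 3, 2]) == \
            haplotype_diversity([2, 5, 3])

    def test_sequence_diversity_aggregates(self):
        panel = two_haplotype_panel(19, 6)
        st = sequence_diversity(panel, "Pout")
        assert st.n == 25 and st.n_haplotypes == 2 and st.s == 1
        assert round(st.hd, 3) == 0.380


class TestHudson:
    def test_complete_sorting(self):
        panel = seq_panel({"a": ["ACGT"] * 5, "b": ["ACGA"] * 5})
        d = hudson_differentiation(panel, "a", "b", n_perm=99, seed=0)
        assert d.fst == pytest.approx(1.0)
        assert d.hst == pytest.approx(1.0)
        assert d.hs == pytest.approx(0.0)

    def test_identical_populations_not_significant(self):
        seqs = ["ACGTAA", "ACGTAT", "ACGAAA", "TCGTAA"] * 3
        panel = seq_panel({"a": seqs, "b": seqs})
        d = hudson_differentiation(panel, "a", "b", n_perm=199, seed=1)
        assert abs(d.kst_star) < 0.05
        assert d.p_kst > 0.05

    def test_monomorphic_pooled_sample_rejected(self):
        panel = seq_panel({"a": ["ACGT"] * 4, "b": ["ACGT"] * 4})
        with pytest.raises(ValueError, match="monomorphic"):
            hudson_differentiation(panel, "a", "b", n_perm=9, seed=0)

    def test_sequence_order_invariance(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(16)]
        pops = ["a"] * 8 + ["b"] * 8
        panel = seq_panel({"a": seqs[:8], "b": seqs[8:]})
        d1 = hudson_differentiation(panel, "a", "b", n_perm=49, seed=3)
        order = rng.permutation(16)
        panel2 = SequencePanel(
            ids=[panel.ids[i] for i in order],
            populations=[panel.populations[i] for i in order],
            regions=panel.regions,
            sequences=[panel.sequences[i] for i in order])
        d2 = hudson_differentiation(panel2, "a", "b", n_perm=49, seed=3)
        assert d1.kst_star == pytest.approx(d2.kst_star, abs=1e-12)
        assert d1.hst == pytest.approx(d2.hst, abs=1e-12)

    def test_no_shared_haplotypes_gives_positive_hst(self):
        panel = seq_panel({"a": ["ACGT", "ACGA"] * 3,
                           "b": ["TCGT", "TCGA"] * 3})
        d = hudson_differentiation(panel, "a", "b", n_perm=99, seed=0)
        assert d.hst > 0

    def test_permutation_determinism(self):
        panel = seq_panel({"a": ["ACGT", "ACGA"] * 3,
                           "b": ["TCGT", "ACGA"] * 3})
        p1 = hudson_differentiation(panel, "a", "b", n_perm=99, seed=7).p_kst
        p2 = hudson_differentiation(panel, "a", "b", n_perm=99, seed=7).p_kst
        assert p1 == p2


class TestNetwork:
    def test_single_step_edge(self):
        table = collapse_haplotypes(seq_panel({"p": ["ACGT", "ACGA"]}))
        net = parsimony_network(table, connection_limit=11)
        assert net.edges == [("H1", "H2", 1)]
        assert len(net.components) == 1

    def test_three_haplotypes_on_a_line(self):
        table = collapse_haplotypes(
            seq_panel({"p": ["AAAA", "AAAT", "AATT"]}))
        net = parsimony_network(table, connection_limit=11)
        # brute-force MST of the 3-node path: edges (H1,H2) and (H2,H3)
        pairs = {frozenset((u, v)) for u, v, _ in net.edges}
        assert pairs == {frozenset(("H1", "H2")), frozenset(("H2", "H3"))}

    def test_connection_limit_splits_clusters(self):
        far = "T" * 12 + "A" * 8
        near = "A" * 20
        near2 = "A" * 19 + "C"
        table = collapse_haplotypes(seq_panel({"p": [near, near2, far]}))
        net = parsimony_network(table, connection_limit=11)
        assert len(net.components) == 2

    def test_intermediate_nodes_inserted(self):
        table = collapse_haplotypes(seq_panel({"p": ["AAAA", "TTAA"]}))
        net = parsimony_network(table, connection_limit=11)
        assert any(n.startswith("i") for n in net.nodes)
        assert all(w <= 1 for _, _, w in net.edges)
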