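"""Chord distance conventions and Neighbour-Joining correctness."""

import numpy as np
import pytest

from tsetsepop.panels import DistanceMatrix
from tsetsepop.tree import (chord_distance, chord_distance_matrix,
                            frequency_table, neighbor_joining,
                            tip_branch_lengths, to_newick)

from conftest import make_panel


def path_distance_matrix(tree, labels):
    """Leaf-to-leaf path lengths of a PopulationTree (test-side oracle)."""
    paths = {}

    def walk(node, dist):
        if not node.children:
            paths[node.name] = dist
            return
        for child, bl in node.children:
            walk(child, dist + [bl])

    # root the distances at the internal root: distance between two leaves is
    # the sum of branch lengths on their paths minus twice the shared prefix
    leaf_paths = {}

    def walk2(node, acc):
        if not node.children:
            leaf_paths[node.name] = acc
            return
        for i, (child, bl) in enumerate(node.children):
            walk2(child, acc + [(id(node), i, bl)])

    walk2(tree.root, [])
    m = len(labels)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = leaf_paths[labels[i]], leaf_paths[labels[j]]
            shared = 0
            for (na, ia, _), (nb, ib, _) in zip(a, b):
                if na == nb and ia == ib:
                    shared += 1
                else:
                    break
            d = sum(bl for *_, bl in a[shared:]) + \
                sum(bl for *_, bl in b[shared:])
            out[i, j] = out[j, i] = d
    return out


class TestChordDistance:
    def test_identical_frequencies_give_zero(self):
        calls = [[(1, 2)], [(1, 1)], [(1, 2)], [(1, 1)]]
        panel = make_panel(calls, ["a", "a", "b", "b"])
        table = frequency_table(panel)
        assert chord_distance(table, "a", "b") == pytest.approx(0.0)

    def test_fixed_difference_single_locus(self):
        calls = [[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]]
        panel = make_panel(calls, ["a", "a", "b", "b"])
        table = frequency_table(panel)
        assert chord_distance(table, "a", "b") == pytest.approx(np.sqrt(2))
        assert chord_distance(table, "a", "b", arc_prefactor=True) == \
            pytest.approx(2 / np.pi * np.sqrt(2))

    def test_symmetry_on_random_tables(self, study_panel):
        table = frequency_table(study_panel)
        pops = study_panel.population_names
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                assert chord_distance(table, pops[i], pops[j]) == \
                    pytest.approx(chord_distance(table, pops[j], pops[i]))

    def test_matrix_properties(self, study_panel):
        dm = chord_distance_matrix(study_panel)
        assert dm.statistic == "chord"
        assert (dm.condensed() > 0).all()


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]]))
        tree = neighbor_joining(dm)
        assert tip_branch_lengths(tree) == pytest.approx(
            {"A": 0.5, "B": 1.5, "C": 2.5})

    def test_additive_five_taxon_recovery(self):
        # distances generated from a known tree:
        # ((A:1,B:2):1.5,C:4,(D:0.5,E:1):2) at an internal root
        labels = list("ABCDE")
        tips = {"A": 1.0, "B": 2.0, "C": 4.0, "D": 0.5, "E": 1.0}
        extra = {("A", "B"): 0, ("D", "E"): 0}
        stem = {"A": 1.5, "B": 1.5, "C": 0.0, "D": 2.0, "E": 2.0}
        m = np.zeros((5, 5))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i == j:
                    continue
                d = tips[x] + tips[y]
                if (x, y) not in (("A", "B"), ("B", "A"),
                                  ("D", "E"), ("E", "D")):
                    d += stem[x] + stem[y]
                m[i, j] = d
        dm = DistanceMatrix(labels, m)
        tree = neighbor_joining(dm)
        assert np.allclose(path_distance_matrix(tree, labels), m, atol=1e-10)
        assert tip_branch_lengths(tree) == pytest.approx(tips)

    def test_skbio_cross_check(self, study_panel):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj
        dm = chord_distance_matrix(study_panel)
        mine = neighbor_joining(dm)
        ref = nj(SkDM(dm.values, ids=dm.labels))
        ref_d = {}
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1:]:
                ref_d[(a, b)] = ref.find(a).distance(ref.find(b))
        mine_d = path_distance_matrix(mine, dm.labels)
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, len(dm.labels)):
                b = dm.labels[j]
                assert mine_d[i, j] == pytest.approx(ref_d[(a, b)],
                                                     abs=1e-8)

    def test_equal_distances_deterministic(self):
        labels = list("ABCD")
        m = np.ones((4, 4)) - np.eye(4)
        t1 = to_newick(neighbor_joining(DistanceMatrix(labels, m)))
        t2 = to_newick(neighbor_joining(DistanceMatrix(labels, m)))
        assert t1 == t2

    def test_label_permutation_invariance(self, study_panel):
        dm = chord_distance_matrix(study_panel)
        perm = [dm.labels[i] for i in (3, 1, 4, 0, 2)]
        t1 = path_distance_matrix(neighbor_joining(dm), dm.labels)
        t2 = path_distance_matrix(neighbor_joining(dm.reorder(perm)),
                                  dm.labels)
        assert np.allclose(t1, t2, atol=1e-10)

    def test_asymmetric_matrix_rejected(self):
        dm = DistanceMatrix(list("ABC"), np.zeros((3, 3)))
        dm.values = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(dm)

    def test_newick_parses_back(self, tmp_path, study_panel):
        from skbio import TreeNode
        import io as _io
        dm = chord_distance_matrix(study_panel)
        nwk = to_newick(neighbor_joining(dm))
        tree = TreeNode.read(_io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == set(dm.labels)
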