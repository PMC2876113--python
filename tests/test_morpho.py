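"""Procrustes alignment, partial warps and Mahalanobis discrimination."""

import numpy as np
import pytest

from tsetsepop.morpho import gpa, mahalanobis_cva, partial_warps
from tsetsepop.panels import LandmarkPanel
from tsetsepop.simulate import simulate_landmarks, study_config


def rand_similarity(rng, cfg):
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return rng.uniform(0.3, 3.0) * cfg @ rot.T + rng.uniform(-10, 10, 2)


def decagon(k=10):
    ang = 2 * np.pi * np.arange(k) / k
    return np.stack([np.cos(ang), np.sin(ang)], axis=1)


class TestGPA:
    def test_identical_up_to_similarity_aligns_exactly(self):
        rng = np.random.default_rng(0)
        base = decagon() + 0.1 * rng.standard_normal((10, 2))
        configs = np.stack([rand_similarity(rng, base) for _ in range(8)])
        res = gpa(LandmarkPanel(ids=[str(i) for i in range(8)],
                                groups=["g"] * 8, configs=configs))
        assert np.allclose(res.aligned, res.aligned[0], atol=1e-9)
        assert np.allclose(res.aligned[0], res.consensus, atol=1e-9)

    def test_alignment_invariant_under_similarity_transforms(self):
        rng = np.random.default_rng(1)
        lm = simulate_landmarks(study_config(1), seed=1)
        res = gpa(lm)
        resid = np.linalg.norm(res.aligned - res.consensus, axis=(1, 2))
        for trial in range(50):
            configs = np.stack([rand_similarity(rng, c)
                                for c in lm.configs])
            res2 = gpa(LandmarkPanel(ids=lm.ids, groups=lm.groups,
                                     configs=configs))
            resid2 = np.linalg.norm(res2.aligned - res2.consensus,
                                    axis=(1, 2))
            assert np.allclose(resid, resid2, atol=1e-10)

    def test_consensus_centred_unit_size(self):
        lm = simulate_landmarks(study_config(2), seed=2)
        res = gpa(lm)
        assert np.allclose(res.consensus.mean(axis=0), 0, atol=1e-12)
        assert np.sqrt((res.consensus ** 2).sum()) == pytest.approx(1.0)

    def test_mirror_image_flagged(self):
        rng = np.random.default_rng(3)
        base = decagon() + 0.2 * rng.standard_normal((10, 2))
        mirrored = base * np.array([1.0, -1.0])
        panel = LandmarkPanel(ids=["a", "b"], groups=["g", "g"],
                              configs=np.stack([base, mirrored]))
        res = gpa(panel)
        resid = np.linalg.norm(res.aligned - res.consensus, axis=(1, 2))
        assert resid.max() > 1e-3       # reflection not allowed
        assert res.poor_fit             # and reported

    def test_degenerate_configuration_rejected(self):
        configs = np.zeros((2, 5, 2))
        configs[1] = decagon(5)
        with pytest.raises(ValueError, match="degenerate"):
            gpa(LandmarkPanel(ids=["a", "b"], groups=["g", "g"],
                              configs=configs))


class TestPartialWarps:
    def test_dimension_is_2k_minus_4(self):
        lm = simulate_landmarks(study_config(3), seed=3)
        sv = partial_warps(gpa(lm))
        assert sv.scores.shape == (lm.n, 16)
        assert sv.n_nonuniform == 14 and sv.n_uniform == 2

    def test_consensus_scores_are_zero(self):
        lm = simulate_landmarks(study_config(4), seed=4)
        res = gpa(lm)
        sv = partial_warps(res)
        consensus_scores = (res.consensus.ravel()
                            - res.consensus.ravel()) @ sv.basis
        assert np.allclose(consensus_scores, 0)

    def test_score_norm_equals_tangent_distance(self):
        lm = simulate_landmarks(study_config(5), seed=5)
        res = gpa(lm)
        sv = partial_warps(res)
        # tangent-space residual after projecting out similarity directions
        k = res.consensus.shape[0]
        ref = res.consensus
        ones, zero = np.ones(k), np.zeros(k)
        sim = np.stack([np.stack([ones, zero], 1).ravel(),
                        np.stack([zero, ones], 1).ravel(),
                        ref.ravel(),
                        np.stack([-ref[:, 1], ref[:, 0]], 1).ravel()], 1)
        q, _ = np.linalg.qr(sim)
        resid = (res.aligned - ref).reshape(lm.n, 2 * k)
        resid = resid - resid @ q @ q.T
        assert np.allclose(np.linalg.norm(sv.scores, axis=1),
                           np.linalg.norm(resid, axis=1), atol=1e-8)

    def test_ordering_invariance(self):
        lm = simulate_landmarks(study_config(6), seed=6)
        sv = partial_warps(gpa(lm))
        order = np.random.default_rng(0).permutation(lm.n)
        lm2 = LandmarkPanel(ids=[lm.ids[i] for i in order],
                            groups=[lm.groups[i] for i in order],
                            configs=lm.configs[order])
        sv2 = partial_warps(gpa(lm2))
        assert np.allclose(np.linalg.norm(sv.scores, axis=1)[order],
                           np.linalg.norm(sv2.scores, axis=1), atol=1e-8)


class TestCVA:
    def test_pythagorean_mahalanobis(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = rng.standard_normal((2 * n, 6))
        X[n:, 0] += 3.0
        X[n:, 1] += 4.0
        labels = ["a"] * n + ["b"] * n
        cva = mahalanobis_cva(X, labels, n_perm=9, seed=0)
        assert cva.d_matrix.values[0, 1] == pytest.approx(5.0, abs=0.1)

    def test_reclassification_counts_sum_to_group_sizes(self):
        lm = simulate_landmarks(study_config(7), seed=7)
        cva = mahalanobis_cva(partial_warps(gpa(lm)), lm.groups,
                              n_perm=19, seed=0)
        for name, n in study_config(7).landmark_groups:
            assert cva.reclassified[name][1] == n

    def test_study_separation_and_significance(self):
        lm = simulate_landmarks(study_config(8), seed=8)
        cva = mahalanobis_cva(partial_warps(gpa(lm)), lm.groups,
                              n_perm=199, seed=1)
        correct = sum(c for c, _ in cva.reclassified.values())
        total = sum(t for _, t in cva.reclassified.values())
        assert 0.60 <= correct / total <= 0.95
        off = cva.p_matrix[np.triu_indices(len(cva.groups), 1)]
        assert (off < 0.05).all()

    def test_no_signal_reclassifies_near_chance_with_loo(self):
        rates = []
        for seed in range(3):
            cfg = study_config(seed)
            cfg.landmark_offset_scale = 0.0
            lm = simulate_landmarks(cfg, seed=seed)
            cva = mahalanobis_cva(partial_warps(gpa(lm)), lm.groups,
                                  n_perm=9, seed=0, leave_one_out=True)
            correct = sum(c for c, _ in cva.reclassified.values())
            total = sum(t for _, t in cva.reclassified.values())
            rates.append(correct / total)
        assert 0.05 <= np.mean(rates) <= 0.40    # chance is 1/5

    def test_invariance_to_linear_transform_of_scores(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 5))
        X[30:] += rng.uniform(0.5, 1.0, 5)
        labels = ["a"] * 30 + ["b"] * 30
        A = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        d1 = mahalanobis_cva(X, labels, n_perm=9, seed=0).d_matrix.values
        d2 = mahalanobis_cva(X @ A, labels, n_perm=9,
                             seed=0).d_matrix.values
        assert np.allclose(d1, d2, atol=1e-8)

    def test_singleton_group_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((21, 4))
        labels = ["a"] * 10 + ["b"] * 10 + ["c"]
        with pytest.warns(UserWarning, match="excluded"):
            cva = mahalanobis_cva(X, labels, n_perm=9, seed=0)
        assert cva.groups == ["a", "b"]
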