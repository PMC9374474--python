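import numpy as np
import pytest

from synfma.merging import (
    decompose_patient_synergy,
    merging_count,
    merging_rate,
    ordered_similarity_matrix,
    per_task_merging_rate,
)
from synfma.standard import DomainError, StandardSynergySet
from synfma.tasks import task_activation
from synfma.types import SynergyDecomposition

from conftest import make_epochs
from test_tasks import nnls_bruteforce


def _orthonormal_std(dim=8, s=4):
    W = np.zeros((dim, s))
    for k in range(s):
        W[2 * k:2 * k + 2, k] = 1.0 / np.sqrt(2)
    return StandardSynergySet(
        W_std=W, muscle_labels=[f"m{i}" for i in range(dim)],
        clusters=[[] for _ in range(s)], participant_support=[7] * s,
    )


class TestDecompose:
    def test_identity_on_standard_column(self):
        std = _orthonormal_std()
        c, cosine = decompose_patient_synergy(std.W_std[:, 2], std)
        expected = np.zeros(4)
        expected[2] = 1.0
        np.testing.assert_allclose(c, expected, atol=1e-9)
        assert cosine == pytest.approx(1.0)

    def test_two_way_merge_closed_form(self):
        # for orthonormal standards, the normalised sum of two of them has
        # NNLS coefficients 1/sqrt(2) on each
        std = _orthonormal_std()
        w = std.W_std[:, 0] + std.W_std[:, 1]
        w = w / np.linalg.norm(w)
        c, cosine = decompose_patient_synergy(w, std)
        np.testing.assert_allclose(c[:2], 1 / np.sqrt(2), atol=1e-9)
        np.testing.assert_allclose(c[2:], 0.0, atol=1e-9)
        assert cosine == pytest.approx(1.0)
        assert merging_count(c) == 2

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            W = rng.uniform(0, 1, size=(6, 4))
            W /= np.linalg.norm(W, axis=0)
            std = StandardSynergySet(
                W_std=W, muscle_labels=[f"m{i}" for i in range(6)],
                clusters=[[] for _ in range(4)], participant_support=[7] * 4,
            )
            w = rng.uniform(0, 1, size=6)
            w /= np.linalg.norm(w)
            c, _ = decompose_patient_synergy(w, std)
            np.testing.assert_allclose(c, nnls_bruteforce(W, w), atol=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            decompose_patient_synergy(np.zeros(8), _orthonormal_std())


class TestMergingCount:
    def test_strict_threshold(self):
        assert merging_count(np.array([0.9, 0.15, 0.05])) == 2
        assert merging_count(np.array([0.1, 0.1, 0.1])) == 0
        assert merging_count(np.zeros(3)) == 0

    def test_threshold_sweep_monotone(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 0.4, size=10)
        counts = [merging_count(c, th) for th in (0.08, 0.1, 0.12)]
        assert counts == sorted(counts, reverse=True)


def _decomposition(W):
    W = W / np.linalg.norm(W, axis=0)
    K = W.shape[1]
    return SynergyDecomposition(W=W, H=np.zeros((K, 2)), K=K, vaf=1.0)


class TestMergingRate:
    def test_identity_patient_rate_one(self):
        std = _orthonormal_std()
        res = merging_rate(_decomposition(std.W_std.copy()), std)
        assert res.merging_rate == pytest.approx(1.0)
        np.testing.assert_array_equal(res.merge_counts, [1, 1, 1, 1])

    def test_pairwise_merges_rate_two(self):
        std = _orthonormal_std(dim=12, s=6)
        cols = []
        for a, b in [(0, 1), (2, 3), (4, 5)]:
            v = std.W_std[:, a] + std.W_std[:, b]
            cols.append(v / np.linalg.norm(v))
        res = merging_rate(_decomposition(np.column_stack(cols)), std)
        assert res.merging_rate == pytest.approx(2.0)

    def test_non_represented_excluded(self):
        std = _orthonormal_std(dim=8, s=3)   # standards span dims 0..5 only
        outside = np.array([0, 0, 0, 0, 0, 0, 1.0, 1.0])
        W = np.column_stack([std.W_std[:, 0], outside / np.linalg.norm(outside)])
        res = merging_rate(_decomposition(W), std)
        assert res.represented.tolist() == [True, False]
        assert res.merging_rate == pytest.approx(1.0)   # mean over represented

    def test_healthy_trial_rate_near_one(self):
        """Synergies extracted from a healthy trial at the planted order are
        in one-to-one correspondence with the cohort's synergy basis."""
        from synfma.extraction import ExtractionConfig, nmf_factorize
        from synfma.preprocessing import (
            PreprocessConfig, epoch_concatenated_envelope, preprocess_emg)
        from synfma.simulate import (
            SimulationConfig, generate_ground_truth, healthy_synergy_set,
            simulate_trial)
        cfg = SimulationConfig()
        truth = generate_ground_truth(cfg, seed=42)
        std = StandardSynergySet(
            W_std=truth.W_true.copy(), muscle_labels=truth.muscle_labels,
            clusters=[[] for _ in range(13)], participant_support=[7] * 13)
        for i in range(2):
            rec = simulate_trial(healthy_synergy_set(truth), truth, cfg,
                                 seed=500 + i, subject_id="H", trial_index=1,
                                 group="healthy", fma_score=None)
            env = preprocess_emg(rec, PreprocessConfig(envelope_rate_hz=25.0))
            mat, _ = epoch_concatenated_envelope(env)
            dec = nmf_factorize(mat, 13,
                                ExtractionConfig(seed=600 + i, n_restarts=10))
            res = merging_rate(dec, std)
            assert res.merging_rate == pytest.approx(1.0, abs=0.2)

    def test_rate_nan_when_nothing_represented(self):
        std = StandardSynergySet(
            W_std=np.array([[1.0], [0.0], [0.0]]),
            muscle_labels=["a", "b", "c"],
            clusters=[[]], participant_support=[7],
        )
        W = np.array([[0.0], [1.0], [0.0]])
        res = merging_rate(_decomposition(W), std)
        assert not res.represented.any()
        assert np.isnan(res.merging_rate)


class TestPerTaskMergingRate:
    def _profile(self, active_matrix):
        epochs = make_epochs(frames_per_item=4)
        S = active_matrix.shape[0]
        coeffs = np.zeros((S, epochs.max_frame))
        for s in range(S):
            for j, e in enumerate(epochs):
                if active_matrix[s, j]:
                    coeffs[s, e.start_frame:e.end_frame] = 0.9
        return task_activation(coeffs, epochs)

    def test_missing_when_no_active_synergy(self):
        std = _orthonormal_std()
        res = merging_rate(_decomposition(std.W_std.copy()), std)
        active = np.zeros((4, 37), dtype=bool)
        active[:, 5] = True   # only item 6 has activity
        rates = per_task_merging_rate(res, self._profile(active))
        assert np.isnan(rates[0])
        assert rates[5] == pytest.approx(1.0)

    def test_single_active_synergy_count(self):
        std = _orthonormal_std(dim=12, s=6)
        v = std.W_std[:, 0] + std.W_std[:, 1] + std.W_std[:, 2]
        W = np.column_stack([v / np.linalg.norm(v)])
        res = merging_rate(_decomposition(W), std)
        active = np.ones((1, 37), dtype=bool)
        rates = per_task_merging_rate(res, self._profile(active))
        np.testing.assert_allclose(rates, 3.0)


class TestOrderedSimilarity:
    def test_identity_is_permutation_diagonal(self):
        std = _orthonormal_std()
        perm = [2, 0, 3, 1]
        sim, order = ordered_similarity_matrix(std, std.W_std[:, perm])
        np.testing.assert_allclose(np.diag(sim), 1.0)

    def test_merged_column_has_two_dark_entries(self):
        std = _orthonormal_std()
        v = std.W_std[:, 0] + std.W_std[:, 1]
        sim, _ = ordered_similarity_matrix(std, (v / np.linalg.norm(v))[:, None])
        assert (sim[:, 0] > 0.7).sum() == 2

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        std = _orthonormal_std()
        W = rng.uniform(0, 1, size=(8, 5))
        W /= np.linalg.norm(W, axis=0)
        sim1, _ = ordered_similarity_matrix(std, W)
        sim2, _ = ordered_similarity_matrix(std, W[:, rng.permutation(5)])
        np.testing.assert_allclose(sim1, sim2, atol=1e-12)
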