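"""Linear-chain CRF: scores, partition, gradient, Viterbi vs enumeration."""

import itertools

import numpy as np
import pytest

from convner import YIDU_SCHEME
from convner.autograd import Tensor
from convner.crf import (CRF, brute_force_best_path, brute_force_log_partition,
                         bio_transition_masks, crf_log_partition, crf_nll,
                         crf_path_score, viterbi_decode)


def random_instance(rng, n_max=6, k_max=5):
    n = int(rng.integers(1, n_max + 1))
    K = int(rng.integers(1, k_max + 1))
    e = rng.standard_normal((n, K))
    A = rng.standard_normal((K + 2, K + 2))
    return e, A


class TestPathScore:
    def test_hand_case_single_position(self):
        e = np.array([[1.0, 2.0]])
        A = np.zeros((4, 4))
        assert crf_path_score(e, [1], A) == pytest.approx(2.0)

    def test_all_zero_scores(self):
        e = np.zeros((3, 2))
        A = np.zeros((4, 4))
        for y in itertools.product(range(2), repeat=3):
            assert crf_path_score(e, list(y), A) == 0.0

    def test_emission_term_is_linear(self, rng):
        e, A = rng.standard_normal((4, 3)), np.zeros((5, 5))
        y = [0, 2, 1, 0]
        assert crf_path_score(2 * e, y, A) == pytest.approx(2 * crf_path_score(e, y, A))

    def test_bad_path_rejected(self):
        with pytest.raises(IndexError):
            crf_path_score(np.zeros((2, 2)), [0, 5], np.zeros((4, 4)))


class TestLogPartition:
    def test_two_equal_paths(self):
        # n=1, K=2, all scores zero: Z = 2
        assert crf_log_partition(np.zeros((1, 2)), np.zeros((4, 4))) == pytest.approx(np.log(2))

    def test_matches_enumeration(self, rng):
        for _ in range(30):
            e, A = random_instance(rng)
            assert crf_log_partition(e, A) == pytest.approx(
                brute_force_log_partition(e, A), abs=1e-9)

    def test_emission_shift_identity(self, rng):
        e, A = rng.standard_normal((5, 3)), rng.standard_normal((5, 5))
        c = 0.73
        assert crf_log_partition(e + c, A) == pytest.approx(
            crf_log_partition(e, A) + 5 * c)

    def test_normalization(self, rng):
        """exp(S - log Z) sums to one over all paths."""
        for _ in range(10):
            e, A = random_instance(rng, n_max=5, k_max=4)
            lz = crf_log_partition(e, A)
            total = sum(np.exp(crf_path_score(e, list(y), A) - lz)
                        for y in itertools.product(range(e.shape[1]), repeat=e.shape[0]))
            assert total == pytest.approx(1.0, abs=1e-6)


class TestNLL:
    def test_single_label_alphabet_loss_zero(self):
        assert crf_nll(np.ones((4, 1)), [0, 0, 0, 0], np.zeros((3, 3))) == pytest.approx(0.0)

    def test_loss_nonnegative(self, rng):
        for _ in range(20):
            e, A = random_instance(rng)
            y = [int(rng.integers(e.shape[1])) for _ in range(e.shape[0])]
            assert crf_nll(e, y, A) >= -1e-12

    def test_gradient_matches_finite_differences(self, rng):
        """Analytic gradients of the batched NLL on a 4 x 3 instance."""
        crf = CRF(3, rng)
        e = rng.standard_normal((1, 4, 3))
        y = np.array([[0, 2, 1, 1]])
        mask = np.ones((1, 4), bool)
        eT = Tensor(e, requires_grad=True)
        crf.nll(eT, y, mask).backward()
        eps = 1e-6
        num = np.zeros_like(e)
        for t in range(4):
            for k in range(3):
                up, down = e.copy(), e.copy()
                up[0, t, k] += eps
                down[0, t, k] -= eps
                num[0, t, k] = (crf.nll(Tensor(up), y, mask).item()
                                - crf.nll(Tensor(down), y, mask).item()) / (2 * eps)
        assert np.max(np.abs(num - eT.grad)) < 1e-4
        # transition parameters too
        gt = crf.trans.grad.copy()
        for i in range(5):
            for j in range(5):
                orig = crf.trans.data[i, j]
                crf.trans.data[i, j] = orig + eps
                up = crf.nll(Tensor(e), y, mask).item()
                crf.trans.data[i, j] = orig - eps
                down = crf.nll(Tensor(e), y, mask).item()
                crf.trans.data[i, j] = orig
                assert abs((up - down) / (2 * eps) - gt[i, j]) < 1e-4


class TestViterbi:
    def test_single_position_argmax(self, rng):
        e = np.array([[0.3, 1.7, -2.0]])
        A = rng.standard_normal((5, 5))
        scores = [crf_path_score(e, [k], A) for k in range(3)]
        assert viterbi_decode(e, A).indices == [int(np.argmax(scores))]

    def test_agrees_with_enumeration(self, rng):
        for _ in range(100):
            e, A = random_instance(rng)
            v = brute = None
            v = viterbi_decode(e, A)
            brute = brute_force_best_path(e, A)
            assert v.score == pytest.approx(brute.score, abs=1e-9)
            assert v.indices == brute.indices

    def test_transition_dominated_hand_case(self):
        # emissions prefer label 1 everywhere, but the 0 -> 0 transition
        # reward outweighs them
        e = np.array([[0.0, 1.0], [0.0, 1.0]])
        A = np.zeros((4, 4))
        A[0, 0] = 10.0
        assert viterbi_decode(e, A).indices == [0, 0]

    def test_tie_break_lowest_index(self):
        e = np.zeros((3, 3))
        A = np.zeros((5, 5))
        assert viterbi_decode(e, A).indices == [0, 0, 0]

    def test_bio_mask_forces_legal_sequences(self, rng):
        scheme = YIDU_SCHEME
        allowed, start_allowed = bio_transition_masks(scheme)
        K = scheme.n_labels
        for _ in range(20):
            n = int(rng.integers(1, 8))
            e = rng.standard_normal((n, K)) * 5
            A = rng.standard_normal((K + 2, K + 2))
            path = viterbi_decode(e, A, start_allowed=start_allowed, allowed=allowed)
            labels = [scheme.labels[i] for i in path.indices]
            scheme.validate_labels(labels)  # raises on any violation


class TestBruteForce:
    def test_size_guard(self):
        with pytest.raises(ValueError):
            brute_force_best_path(np.zeros((20, 5)), np.zeros((7, 7)))

    def test_single_label(self):
        lp = brute_force_best_path(np.ones((3, 1)), np.zeros((3, 3)))
        assert lp.indices == [0, 0, 0]


class TestBatchedCRF:
    def test_batched_matches_single_sentence(self, rng):
        crf = CRF(4, rng)
        e = rng.standard_normal((3, 6, 4))
        mask = np.zeros((3, 6), bool)
        lengths = [6, 4, 1]
        for b, n in enumerate(lengths):
            mask[b, :n] = True
        lz = crf.log_partition(Tensor(e), mask).data
        for b, n in enumerate(lengths):
            assert lz[b] == pytest.approx(crf_log_partition(e[b, :n], crf.trans.data))
        y = rng.integers(0, 4, size=(3, 6))
        ps = crf.path_score(Tensor(e), y, mask).data
        for b, n in enumerate(lengths):
            assert ps[b] == pytest.approx(
                crf_path_score(e[b, :n], y[b, :n], crf.trans.data))

    def test_decode_respects_lengths(self, rng):
        crf = CRF(3, rng)
        e = rng.standard_normal((2, 5, 3))
        mask = np.array([[1, 1, 1, 1, 1], [1, 1, 0, 0, 0]], bool)
        paths = crf.decode(e, mask)
        assert len(paths[0]) == 5 and len(paths[1]) == 2
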