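"""Linear-chain conditional random field, written from scratch.

A label path y over a length-n sentence is scored

    S(X, y) = sum_i A[y_i, y_{i+1}] + sum_i P[i, y_i]

with A a transition matrix over the K labels plus two extra states
(start, stop) and P the per-position emission scores.  Training
maximises the log-likelihood log p(y|X) = S(X, y) - log Z with the
partition Z computed by the forward recursion in log space; decoding
uses the Viterbi dynamic program.  Exhaustive-enumeration versions of
both quantities are provided for small instances and serve as
independent oracles.

Tie-breaking in Viterbi is deterministic: at every backtrack step the
lowest label index among equal-scoring predecessors is taken (and the
lowest final label); the brute-force search applies the same rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp as _np_logsumexp

from .autograd import Tensor, gather2, gather_labels, logsumexp
from .corpus import LabelScheme
from .nn import Module, Parameter

__all__ = [
    "LabelPath", "CRF", "crf_path_score", "crf_log_partition", "crf_nll",
    "viterbi_decode", "brute_force_best_path", "brute_force_log_partition",
    "bio_transition_masks",
]

NEG = -1e30  # effective -inf that keeps log-space arithmetic NaN-free


@dataclass
class LabelPath:
    indices: list[int]
    score: float


def bio_transition_masks(scheme: LabelScheme) -> tuple[np.ndarray, np.ndarray]:
    """(allowed (K, K), start_allowed (K,)) boolean masks of BIO legality."""
    return scheme.transition_legality(), scheme.start_legality()


def _check(e: np.ndarray, trans: np.ndarray) -> tuple[int, int]:
    e = np.asarray(e, dtype=float)
    n, K = e.shape
    if trans.shape != (K + 2, K + 2):
        raise ValueError(f"transition matrix must be ({K + 2}, {K + 2})")
    return n, K


def crf_path_score(e, y, trans) -> float:
    """S(X, y): start->y_1, inter-label and y_n->stop transitions plus
    the emission score of every position."""
    e = np.asarray(e, dtype=float)
    trans = np.asarray(trans, dtype=float)
    n, K = _check(e, trans)
    y = [int(v) for v in (y.indices if isinstance(y, LabelPath) else y)]
    if len(y) != n:
        raise ValueError("path length must equal sentence length")
    if any(not 0 <= v < K for v in y):
        raise IndexError("label index out of range")
    start, stop = K, K + 1
    s = trans[start, y[0]]
    for t in range(1, n):
        s += trans[y[t - 1], y[t]]
    s += trans[y[-1], stop]
    s += sum(e[t, y[t]] for t in range(n))
    return float(s)


def crf_log_partition(e, trans) -> float:
    """log sum over all K^n paths of exp S, by the log-space forward
    recursion (log-sum-exp at every step)."""
    e = np.asarray(e, dtype=float)
    trans = np.asarray(trans, dtype=float)
    n, K = _check(e, trans)
    start, stop = K, K + 1
    alpha = trans[start, :K] + e[0]
    for t in range(1, n):
        alpha = _np_logsumexp(alpha[:, None] + trans[:K, :K], axis=0) + e[t]
    return float(_np_logsumexp(alpha + trans[:K, stop]))


def crf_nll(e, y, trans) -> float:
    """-log p(y|X) = log Z - S(X, y); nonnegative."""
    return crf_log_partition(e, trans) - crf_path_score(e, y, trans)


def viterbi_decode(e, trans, start_allowed: np.ndarray | None = None,
                   allowed: np.ndarray | None = None) -> LabelPath:
    """Maximum-scoring path by dynamic programming.

    `allowed`/`start_allowed` optionally forbid transitions (e.g. the
    BIO legality mask); forbidden moves score an effective -inf and are
    never selected.
    """
    e = np.asarray(e, dtype=float)
    trans = np.asarray(trans, dtype=float)
    n, K = _check(e, trans)
    start, stop = K, K + 1
    t_ss = trans[:K, :K].copy()
    if allowed is not None:
        t_ss = np.where(allowed, t_ss, NEG)
    score = trans[start, :K] + e[0]
    if start_allowed is not None:
        score = np.where(start_allowed, score, NEG)
    back = np.zeros((n, K), dtype=np.int64)
    for t in range(1, n):
        m = score[:, None] + t_ss
        back[t] = np.argmax(m, axis=0)  # first max = lowest index tie-break
        score = m[back[t], np.arange(K)] + e[t]
    final = score + trans[:K, stop]
    last = int(np.argmax(final))
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return LabelPath(path, crf_path_score(e, path, trans))


def brute_force_best_path(e, trans, start_allowed=None, allowed=None,
                          limit: int = 10 ** 6) -> LabelPath:
    """Exhaustive-enumeration argmax over all K^n paths (test oracle).

    Ties resolve to the path that is smallest read back-to-front,
    matching the Viterbi backtrack rule.
    """
    e = np.asarray(e, dtype=float)
    trans = np.asarray(trans, dtype=float)
    n, K = _check(e, trans)
    if K ** n > limit:
        raise ValueError(f"instance too large: K^n = {K ** n} > {limit}")
    best: tuple[float, tuple[int, ...]] | None = None
    for y in itertools.product(range(K), repeat=n):
        if start_allowed is not None and not start_allowed[y[0]]:
            continue
        if allowed is not None and any(not allowed[a, b] for a, b in zip(y, y[1:])):
            continue
        s = crf_path_score(e, y, trans)
        key = tuple(reversed(y))
        if best is None or s > best[0] or (s == best[0] and key < tuple(reversed(best[1]))):
            best = (s, y)
    if best is None:
        raise ValueError("no legal path exists under the given masks")
    return LabelPath(list(best[1]), best[0])


def brute_force_log_partition(e, trans, limit: int = 10 ** 6) -> float:
    """log of the explicit sum over all K^n path scores (test oracle)."""
    e = np.asarray(e, dtype=float)
    trans = np.asarray(trans, dtype=float)
    n, K = _check(e, trans)
    if K ** n > limit:
        raise ValueError(f"instance too large: K^n = {K ** n} > {limit}")
    scores = [crf_path_score(e, y, trans)
              for y in itertools.product(range(K), repeat=n)]
    return float(_np_logsumexp(scores))


class CRF(Module):
    """Trainable CRF layer with batched loss and decoding.

    The transition matrix is (K+2) x (K+2) with start = K and stop =
    K+1; emissions never cover the two extra states.  The BIO hard mask
    (built from the label scheme) is applied at decode time by default
    and left out of the partition during training (soft training, hard
    decoding).
    """

    def __init__(self, n_labels: int, rng: np.random.Generator,
                 scheme: LabelScheme | None = None, hard_mask_decode: bool = True):
        self.K = int(n_labels)
        self.trans = Parameter(rng.normal(0.0, 0.1, size=(self.K + 2, self.K + 2)))
        self.hard_mask_decode = hard_mask_decode
        if scheme is not None:
            if scheme.n_labels != n_labels:
                raise ValueError("scheme label count mismatch")
            self.allowed, self.start_allowed = bio_transition_masks(scheme)
        else:
            self.allowed = self.start_allowed = None

    @property
    def START(self) -> int:
        return self.K

    @property
    def STOP(self) -> int:
        return self.K + 1

    # -- batched differentiable pieces ---------------------------------
    def log_partition(self, e: Tensor, mask: np.ndarray) -> Tensor:
        """(B, L, K) emissions + (B, L) mask -> (B,) log Z."""
        B, L, K = e.shape
        t_ss = self.trans[tuple([slice(0, K), slice(0, K)])]
        alpha = self.trans[self.START][0:K] + e[:, 0, :]
        for t in range(1, L):
            m = Tensor(np.asarray(mask[:, t:t + 1], dtype=np.float64))
            scores = alpha.reshape(B, K, 1) + t_ss + e[:, t, :].reshape(B, 1, K)
            new = logsumexp(scores, axis=1)
            alpha = new * m + alpha * (1.0 - m)
        final = alpha + self.trans[tuple([slice(0, K), self.STOP])]
        return logsumexp(final, axis=1)

    def path_score(self, e: Tensor, y: np.ndarray, mask: np.ndarray) -> Tensor:
        """(B,) gold-path scores; padded positions are excluded and the
        stop transition is taken from the last real position."""
        B, L, K = e.shape
        y = np.asarray(y, dtype=np.int64)
        mf = np.asarray(mask, dtype=np.float64)
        em = gather_labels(e, y) * Tensor(mf)
        total = em.sum(axis=1)
        total = total + gather2(self.trans, np.full(B, self.START), y[:, 0])
        if L > 1:
            inter = gather2(self.trans, y[:, :-1], y[:, 1:]) * Tensor(mf[:, 1:])
            total = total + inter.sum(axis=1)
        lengths = mask.astype(np.int64).sum(axis=1)
        last = y[np.arange(B), lengths - 1]
        total = total + gather2(self.trans, last, np.full(B, self.STOP))
        return total

    def nll(self, e: Tensor, y: np.ndarray, mask: np.ndarray) -> Tensor:
        """Mean over the batch of log Z - S(X, y_gold); >= 0."""
        return (self.log_partition(e, mask) - self.path_score(e, y, mask)).mean()

    # -- decoding -------------------------------------------------------
    def decode(self, emissions: np.ndarray, mask: np.ndarray) -> list[list[int]]:
        """Batched Viterbi on raw emission arrays; returns one index
        path per sentence, truncated to its real length."""
        emissions = np.asarray(emissions, dtype=float)
        out = []
        allowed = self.allowed if self.hard_mask_decode else None
        start_allowed = self.start_allowed if self.hard_mask_decode else None
        for b in range(emissions.shape[0]):
            n = int(mask[b].sum())
            path = viterbi_decode(emissions[b, :n], self.trans.data,
                                  start_allowed=start_allowed, allowed=allowed)
            out.append(path.indices)
        return out
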