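"""Bidirectional LSTM context encoder.

The cell follows the classic six-equation update with per-gate weight
matrices acting on the concatenation [h_{t-1}, x_t]:

    f_t = sigmoid(W_f . [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(W_i . [h_{t-1}, x_t] + b_i)        (input gate)
    C~_t = tanh(W_C . [h_{t-1}, x_t] + b_C)          (candidate state)
    C_t = f_t * C_{t-1} + i_t * C~_t                 (cell state)
    o_t = sigmoid(W_o . [h_{t-1}, x_t] + b_o)        (output gate)
    h_t = o_t * tanh(C_t)                            (hidden state)

Forward and backward directions have independent parameter sets; their
hidden states are concatenated per position.  Masked (padding)
positions contribute zero state: h and C are zeroed there, so the
backward pass effectively starts at the last real character.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, stack
from .nn import Module, Parameter, glorot

__all__ = ["LSTMDirectionParams", "lstm_step", "BiLSTM"]


class LSTMDirectionParams(Module):
    """Gate weights of one direction: W_* of shape (H + D_in, H)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        d = in_dim + hidden
        self.W_f = Parameter(glorot(rng, d, hidden))
        self.W_i = Parameter(glorot(rng, d, hidden))
        self.W_C = Parameter(glorot(rng, d, hidden))
        self.W_o = Parameter(glorot(rng, d, hidden))
        # forget-gate bias starts at 1 so early training does not forget
        self.b_f = Parameter(np.ones(hidden))
        self.b_i = Parameter(np.zeros(hidden))
        self.b_C = Parameter(np.zeros(hidden))
        self.b_o = Parameter(np.zeros(hidden))
        self.hidden = hidden
        self.in_dim = in_dim


def lstm_step(x_t: Tensor, h_prev: Tensor, c_prev: Tensor,
              params: LSTMDirectionParams) -> tuple[Tensor, Tensor]:
    """One cell update; exactly the six equations above."""
    z = concat([h_prev, x_t], axis=-1)
    f = (z @ params.W_f + params.b_f).sigmoid()
    i = (z @ params.W_i + params.b_i).sigmoid()
    c_tilde = (z @ params.W_C + params.b_C).tanh()
    c_t = f * c_prev + i * c_tilde
    o = (z @ params.W_o + params.b_o).sigmoid()
    h_t = o * c_t.tanh()
    return h_t, c_t


class BiLSTM(Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTMDirectionParams(in_dim, hidden, rng)
        self.bwd = LSTMDirectionParams(in_dim, hidden, rng)
        self.hidden = hidden

    def _run_direction(self, x: Tensor, mask: np.ndarray,
                       params: LSTMDirectionParams, reverse: bool) -> Tensor:
        B, L, _ = x.shape
        h = Tensor(np.zeros((B, params.hidden)))
        c = Tensor(np.zeros((B, params.hidden)))
        order = range(L - 1, -1, -1) if reverse else range(L)
        outs: list[Tensor | None] = [None] * L
        for t in order:
            m = Tensor(np.asarray(mask[:, t:t + 1], dtype=np.float64))
            h_new, c_new = lstm_step(x[:, t, :], h, c, params)
            h = h_new * m
            c = c_new * m
            outs[t] = h
        return stack(outs, axis=1)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """(B, L, C) + (B, L) mask -> (B, L, 2*hidden)."""
        fwd = self._run_direction(x, mask, self.fwd, reverse=False)
        bwd = self._run_direction(x, mask, self.bwd, reverse=True)
        return concat([fwd, bwd], axis=-1)
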