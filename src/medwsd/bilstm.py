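"""Two-layer bidirectional LSTM context encoder.

An LSTM cell follows the classic gated update

    i_t = sigma(W_xi x_t + W_hi h_{t-1} + b_i)
    f_t = sigma(W_xf x_t + W_hf h_{t-1} + b_f)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = sigma(W_xo x_t + W_ho h_{t-1} + b_o)
    h_t = o_t * tanh(c_t)

with independent parameters for the forward and backward directions; the
two directions' hidden states are concatenated per time step, so one
bidirectional layer with hidden size H per direction outputs T x 2H.
Dropout (inverted scaling) is applied between layer 1 and layer 2 during
training only.

Padded positions are handled by mask gating: the recurrent state simply
carries through a masked step, and masked output rows are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat, stack_time
from .encoder_base import EncoderOutputs

__all__ = [
    "LSTMParams",
    "LSTMState",
    "lstm_cell_step",
    "bilstm_layer",
    "encode_bilstm",
    "BiLSTMEncoder",
]


@dataclass
class LSTMParams:
    """Gate weights of one LSTM direction (input dim d, hidden size H)."""

    W_xi: Tensor
    W_xf: Tensor
    W_xc: Tensor
    W_xo: Tensor
    W_hi: Tensor
    W_hf: Tensor
    W_hc: Tensor
    W_ho: Tensor
    b_i: Tensor
    b_f: Tensor
    b_c: Tensor
    b_o: Tensor

    @property
    def hidden_size(self) -> int:
        return self.W_hi.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_xi.shape[0]

    @classmethod
    def init(cls, input_size: int, hidden_size: int, rng: np.random.Generator) -> "LSTMParams":
        """Uniform(+-1/sqrt(H)) init, zero initial states elsewhere."""
        s = 1.0 / np.sqrt(hidden_size)

        def w(r, c):
            return Tensor(rng.uniform(-s, s, size=(r, c)), requires_grad=True)

        def b():
            return Tensor(np.zeros((1, hidden_size)), requires_grad=True)

        return cls(
            W_xi=w(input_size, hidden_size), W_xf=w(input_size, hidden_size),
            W_xc=w(input_size, hidden_size), W_xo=w(input_size, hidden_size),
            W_hi=w(hidden_size, hidden_size), W_hf=w(hidden_size, hidden_size),
            W_hc=w(hidden_size, hidden_size), W_ho=w(hidden_size, hidden_size),
            b_i=b(), b_f=b(), b_c=b(), b_o=b(),
        )

    def tensors(self) -> list[Tensor]:
        return [
            self.W_xi, self.W_xf, self.W_xc, self.W_xo,
            self.W_hi, self.W_hf, self.W_hc, self.W_ho,
            self.b_i, self.b_f, self.b_c, self.b_o,
        ]


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


def _cell(x_t: Tensor, h: Tensor, c: Tensor, p: LSTMParams) -> tuple[Tensor, Tensor]:
    """One gated update on a (B, d) input; returns (h_t, c_t)."""
    i = (x_t @ p.W_xi + h @ p.W_hi + p.b_i).sigmoid()
    f = (x_t @ p.W_xf + h @ p.W_hf + p.b_f).sigmoid()
    g = (x_t @ p.W_xc + h @ p.W_hc + p.b_c).tanh()
    c_t = f * c + i * g
    o = (x_t @ p.W_xo + h @ p.W_ho + p.b_o).sigmoid()
    h_t = o * c_t.tanh()
    return h_t, c_t


def lstm_cell_step(x_t: np.ndarray, state: LSTMState, p: LSTMParams) -> LSTMState:
    """Apply one LSTM cell update to a single input vector."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (p.input_size,):
        raise ValueError(f"expected input of shape ({p.input_size},), got {x_t.shape}")
    h = Tensor(state.h.reshape(1, -1))
    c = Tensor(state.c.reshape(1, -1))
    h_t, c_t = _cell(Tensor(x_t.reshape(1, -1)), h, c, p)
    return LSTMState(h=h_t.data.ravel(), c=c_t.data.ravel())


def _direction(X: Tensor, mask: np.ndarray, p: LSTMParams, reverse: bool) -> list[Tensor]:
    """Run one direction over a padded batch; returns per-step (B, H) outputs.

    The state carries through masked steps unchanged, which makes the
    backward direction consume exactly the reversed *valid* subsequence;
    masked output rows are zeroed.
    """
    B, T, _ = X.shape
    H = p.hidden_size
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    order = range(T - 1, -1, -1) if reverse else range(T)
    outs: dict[int, Tensor] = {}
    for t in order:
        m = Tensor(mask[:, t : t + 1].astype(float))
        h_new, c_new = _cell(X[:, t, :], h, c, p)
        h = h_new * m + h * (1.0 - m)
        c = c_new * m + c * (1.0 - m)
        outs[t] = h_new * m
    return [outs[t] for t in range(T)]


def bilstm_layer_batch(
    X: np.ndarray | Tensor, mask: np.ndarray, p_fwd: LSTMParams, p_bwd: LSTMParams
) -> Tensor:
    """One bidirectional layer on a (B, T, d) batch -> (B, T, 2H) tensor."""
    if not mask.any(axis=1).all():
        raise ValueError("every sequence in the batch must have a valid position")
    X = X if isinstance(X, Tensor) else Tensor(X)
    fwd = _direction(X, mask, p_fwd, reverse=False)
    bwd = _direction(X, mask, p_bwd, reverse=True)
    steps = [concat([f, b], axis=-1) for f, b in zip(fwd, bwd)]
    return stack_time(steps)


def bilstm_layer(
    X: np.ndarray, mask: np.ndarray, p_fwd: LSTMParams, p_bwd: LSTMParams
) -> np.ndarray:
    """Single-sequence convenience wrapper: (T, d) -> (T, 2H)."""
    out = bilstm_layer_batch(X[None, :, :], np.asarray(mask, dtype=bool)[None, :], p_fwd, p_bwd)
    return out.data[0]


def _dropout(Y: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    keep = (rng.random(Y.shape) >= rate).astype(float) / (1.0 - rate)
    return Y * Tensor(keep)


class BiLSTMEncoder:
    """Two stacked bidirectional layers with inter-layer dropout.

    Output dimension D equals 2H of layer 2; by default H is chosen so
    that D matches the input embedding dimension, keeping the two encoder
    families interchangeable under the same head.
    """

    def __init__(
        self,
        input_size: int,
        hidden_size: int = 100,
        dropout: float = 0.5,
        input_scale: float = 1.0,
        rng: np.random.Generator | None = None,
    ):
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        rng = rng or np.random.default_rng(0)
        self.hidden_size = hidden_size
        self.dropout = dropout
        self.input_scale = float(input_scale)
        self.l1_fwd = LSTMParams.init(input_size, hidden_size, rng)
        self.l1_bwd = LSTMParams.init(input_size, hidden_size, rng)
        self.l2_fwd = LSTMParams.init(2 * hidden_size, hidden_size, rng)
        self.l2_bwd = LSTMParams.init(2 * hidden_size, hidden_size, rng)

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden_size

    def parameters(self) -> list[Tensor]:
        return [
            t
            for p in (self.l1_fwd, self.l1_bwd, self.l2_fwd, self.l2_bwd)
            for t in p.tensors()
        ]

    def forward_batch(
        self,
        X: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Return per-layer output tensors (Y, Z), each (B, T, 2H)."""
        Y = bilstm_layer_batch(X * self.input_scale, mask, self.l1_fwd, self.l1_bwd)
        Y_in = Y
        if training and self.dropout > 0.0:
            Y_in = _dropout(Y, self.dropout, rng or np.random.default_rng(0))
        Z = bilstm_layer_batch(Y_in, mask, self.l2_fwd, self.l2_bwd)
        return Y, Z


def encode_bilstm(
    X: np.ndarray,
    mask: np.ndarray,
    encoder: BiLSTMEncoder,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> EncoderOutputs:
    """Functional single-sequence wrapper producing numpy ``EncoderOutputs``."""
    mask = np.asarray(mask, dtype=bool)
    Y, Z = encoder.forward_batch(X[None, :, :], mask[None, :], training=training, rng=rng)
    return EncoderOutputs(Y=Y.data[0], Z=Z.data[0], mask=mask)
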