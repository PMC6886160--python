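"""Two-layer self-attention (Transformer-encoder) context encoder.

Each encoder layer applies multi-head scaled dot-product self-attention
followed by a position-wise feed-forward network, each sub-layer wrapped
in a residual connection with post-norm layer normalization:

    A   = LayerNorm(X + MultiHead(X))
    out = LayerNorm(A + FFN(A))

Head projections use d_q = d_k = d_v = d_model / h; the FFN is two
d_model x d_model linear maps with a ReLU between them, so every
sub-layer output is again T x d_model. Token order enters only through
the fixed sinusoidal positional encoding added to the input embeddings
before layer 1.

Padding is masked at the keys: masked key columns receive a -1e30
additive score, which underflows to exactly zero attention weight; masked
output rows are zeroed after each full layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat, softmax
from .encoder_base import EncoderOutputs

__all__ = [
    "AttentionParams",
    "FFNParams",
    "EncoderLayerParams",
    "positional_encoding",
    "scaled_dot_product_attention",
    "multi_head_attention",
    "positionwise_ffn",
    "encoder_layer",
    "encode_attention",
    "AttentionEncoder",
]

_NEG = -1e30
_LN_EPS = 1e-6


@dataclass
class AttentionParams:
    """Per-head query/key/value projections plus the output projection."""

    W_q: list[Tensor]  # h matrices, each d_model x d_k
    W_k: list[Tensor]
    W_v: list[Tensor]
    W_o: Tensor  # (h * d_v) x d_model
    n_heads: int

    @classmethod
    def init(cls, d_model: int, n_heads: int, rng: np.random.Generator) -> "AttentionParams":
        if d_model % n_heads != 0:
            raise ValueError(f"head count {n_heads} must divide d_model={d_model}")
        d_k = d_model // n_heads
        s = 1.0 / np.sqrt(d_model)

        def w(r, c):
            return Tensor(rng.uniform(-s, s, size=(r, c)), requires_grad=True)

        return cls(
            W_q=[w(d_model, d_k) for _ in range(n_heads)],
            W_k=[w(d_model, d_k) for _ in range(n_heads)],
            W_v=[w(d_model, d_k) for _ in range(n_heads)],
            W_o=w(n_heads * d_k, d_model),
            n_heads=n_heads,
        )

    def tensors(self) -> list[Tensor]:
        return [*self.W_q, *self.W_k, *self.W_v, self.W_o]


@dataclass
class FFNParams:
    W_1: Tensor
    b_1: Tensor
    W_2: Tensor
    b_2: Tensor

    @classmethod
    def init(cls, d_model: int, rng: np.random.Generator) -> "FFNParams":
        s = 1.0 / np.sqrt(d_model)
        return cls(
            W_1=Tensor(rng.uniform(-s, s, size=(d_model, d_model)), requires_grad=True),
            b_1=Tensor(np.zeros((1, 1, d_model)), requires_grad=True),
            W_2=Tensor(rng.uniform(-s, s, size=(d_model, d_model)), requires_grad=True),
            b_2=Tensor(np.zeros((1, 1, d_model)), requires_grad=True),
        )

    def tensors(self) -> list[Tensor]:
        return [self.W_1, self.b_1, self.W_2, self.b_2]


@dataclass
class EncoderLayerParams:
    attention: AttentionParams
    ffn: FFNParams
    ln1_gain: Tensor
    ln1_bias: Tensor
    ln2_gain: Tensor
    ln2_bias: Tensor

    @classmethod
    def init(cls, d_model: int, n_heads: int, rng: np.random.Generator) -> "EncoderLayerParams":
        one = lambda: Tensor(np.ones((1, 1, d_model)), requires_grad=True)  # noqa: E731
        zero = lambda: Tensor(np.zeros((1, 1, d_model)), requires_grad=True)  # noqa: E731
        return cls(
            attention=AttentionParams.init(d_model, n_heads, rng),
            ffn=FFNParams.init(d_model, rng),
            ln1_gain=one(), ln1_bias=zero(), ln2_gain=one(), ln2_bias=zero(),
        )

    def tensors(self) -> list[Tensor]:
        return [
            *self.attention.tensors(), *self.ffn.tensors(),
            self.ln1_gain, self.ln1_bias, self.ln2_gain, self.ln2_bias,
        ]


def positional_encoding(T: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal position matrix, positions counted from 0.

    pe[t, 2i] = sin(t / 10000^(2i/d_model)),
    pe[t, 2i+1] = cos(t / 10000^(2i/d_model)) — sine/cosine pairs share
    the same angular frequency, so a fixed positional offset acts on each
    pair as a plane rotation.
    """
    if d_model % 2 != 0:
        raise ValueError("d_model must be even for sin/cos pairing")
    t = np.arange(T)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angle = t / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((T, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _mask_bias(mask: np.ndarray) -> np.ndarray:
    """(B, T) validity -> (B, 1, T) additive key-score bias (0 or -1e30)."""
    return np.where(mask[:, None, :], 0.0, _NEG)


def sdpa_batch(Q: Tensor, K: Tensor, V: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """Batched Softmax(QK^T/sqrt(d_k))V; returns (output, attention weights)."""
    d_k = Q.shape[-1]
    if not mask.any(axis=-1).all():
        raise ValueError("a query row with zero valid keys is undefined")
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k)) + Tensor(_mask_bias(mask))
    weights = softmax(scores, axis=-1)
    return weights @ V, weights


def scaled_dot_product_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Single-sequence attention on (T, d) matrices."""
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("query and key dimensions must match")
    if mask is None:
        mask = np.ones(K.shape[0], dtype=bool)
    out, _ = sdpa_batch(
        Tensor(Q[None]), Tensor(K[None]), Tensor(V[None]), np.asarray(mask, bool)[None]
    )
    return out.data[0]


def attention_weights(Q: np.ndarray, K: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """The softmax weight matrix itself (for inspection and testing)."""
    if mask is None:
        mask = np.ones(K.shape[0], dtype=bool)
    _, w = sdpa_batch(
        Tensor(Q[None]), Tensor(K[None]), Tensor(np.zeros_like(Q)[None]),
        np.asarray(mask, bool)[None],
    )
    return w.data[0]


def multi_head_batch(X: Tensor, p: AttentionParams, mask: np.ndarray) -> Tensor:
    heads = []
    for i in range(p.n_heads):
        out, _ = sdpa_batch(X @ p.W_q[i], X @ p.W_k[i], X @ p.W_v[i], mask)
        heads.append(out)
    return concat(heads, axis=-1) @ p.W_o


def multi_head_attention(X: np.ndarray, p: AttentionParams, mask: np.ndarray | None = None) -> np.ndarray:
    """Single-sequence multi-head attention: (T, d_model) -> (T, d_model)."""
    if mask is None:
        mask = np.ones(X.shape[0], dtype=bool)
    out = multi_head_batch(Tensor(X[None]), p, np.asarray(mask, bool)[None])
    return out.data[0]


def ffn_batch(Z: Tensor, p: FFNParams) -> Tensor:
    return (Z @ p.W_1 + p.b_1).relu() @ p.W_2 + p.b_2


def positionwise_ffn(Z: np.ndarray, p: FFNParams) -> np.ndarray:
    """max(0, z W_1 + b_1) W_2 + b_2 applied independently at each position."""
    return ffn_batch(Tensor(Z[None]), p).data[0]


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
    """Normalize each position's vector to zero mean / unit variance."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + _LN_EPS) ** -0.5 * gain + bias


def encoder_layer_batch(X: Tensor, p: EncoderLayerParams, mask: np.ndarray) -> Tensor:
    A = layer_norm(X + multi_head_batch(X, p.attention, mask), p.ln1_gain, p.ln1_bias)
    return layer_norm(A + ffn_batch(A, p.ffn), p.ln2_gain, p.ln2_bias)


def encoder_layer(X: np.ndarray, p: EncoderLayerParams, mask: np.ndarray | None = None) -> np.ndarray:
    """Single-sequence encoder layer: LayerNorm(X+MHA(X)) then LayerNorm(·+FFN(·))."""
    if mask is None:
        mask = np.ones(X.shape[0], dtype=bool)
    return encoder_layer_batch(Tensor(X[None]), p, np.asarray(mask, bool)[None]).data[0]


def pe_matched_scale(vectors: np.ndarray) -> float:
    """Input multiplier that matches the embedding RMS to the PE's RMS.

    The sinusoidal position matrix has fixed RMS 1/sqrt(2) per entry,
    while frozen pre-trained embeddings arrive at an arbitrary scale; if
    they are much smaller, X + PE is dominated by position and the
    content signal is lost. Scaling the inputs so their RMS equals the
    PE's keeps the two contributions commensurate.
    """
    rms = float(np.sqrt(np.mean(np.square(vectors))))
    if rms == 0.0:
        return 1.0
    return (1.0 / np.sqrt(2.0)) / rms


class AttentionEncoder:
    """A stack of two identical encoder layers over PE-augmented inputs."""

    def __init__(
        self,
        d_model: int,
        n_heads: int = 2,
        use_pe: bool = True,
        input_scale: float = 1.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.d_model = d_model
        self.n_heads = n_heads
        self.use_pe = use_pe
        self.input_scale = float(input_scale)
        self.layer1 = EncoderLayerParams.init(d_model, n_heads, rng)
        self.layer2 = EncoderLayerParams.init(d_model, n_heads, rng)

    @property
    def output_dim(self) -> int:
        return self.d_model

    def parameters(self) -> list[Tensor]:
        return [*self.layer1.tensors(), *self.layer2.tensors()]

    def forward_batch(
        self,
        X: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Return the two layers' outputs (Y, Z), each (B, T, d_model)."""
        del training, rng  # the attention stack applies no dropout
        B, T, d = X.shape
        if d != self.d_model:
            raise ValueError(f"input dim {d} != d_model {self.d_model}")
        X_in = X * self.input_scale
        if self.use_pe:
            X_in = X_in + positional_encoding(T, d)[None]
        m3 = Tensor(mask[:, :, None].astype(float))
        Y = encoder_layer_batch(Tensor(X_in), self.layer1, mask) * m3
        Z = encoder_layer_batch(Y, self.layer2, mask) * m3
        return Y, Z


def encode_attention(
    X: np.ndarray, mask: np.ndarray, encoder: AttentionEncoder
) -> EncoderOutputs:
    """Functional single-sequence wrapper producing numpy ``EncoderOutputs``."""
    mask = np.asarray(mask, dtype=bool)
    Y, Z = encoder.forward_batch(X[None], mask[None])
    return EncoderOutputs(Y=Y.data[0], Z=Z.data[0], mask=mask)
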