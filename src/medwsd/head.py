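"""Upper layer: layer combination, time max-pooling, hint, classifier.

The two encoder layer outputs Y and Z (each T x D) are combined by one of
four structures:

    direct        H = Z                      (T x D)
    weighted_sum  H = lam*Y + (1-lam)*Z      (T x D, lam in [0,1] trainable)
    concat_time   H = [Y; Z] along time      (2T x D)
    concat_vector H = [Y, Z] along features  (T x 2D)

then max-pooled over time (masked rows excluded) to a context vector h of
length D — or 2D for concat_vector. Optionally the target word's
pre-trained embedding x_k is concatenated as a "hint", xi = [h, x_k],
re-emphasizing which word is being disambiguated; this helps a universal
model trained on many words and tends to be redundant for word-specific
models. The (hinted) vector passes through dense layers of 256 and 64
ReLU units and a softmax over the sense labels.

The mixing weight lambda is stored unconstrained and squashed through a
logistic, keeping it in (0, 1) while remaining trainable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat, log_softmax, softmax

__all__ = ["HeadConfig", "WSDHead", "combine_layers", "max_pool_time", "apply_hint", "classify"]

STRUCTURES = ("direct", "weighted_sum", "concat_time", "concat_vector")
_NEG = -1e30


@dataclass(frozen=True)
class HeadConfig:
    structure: str = "concat_time"
    use_hint: bool = False
    dense_sizes: tuple[int, int] = (256, 64)
    n_labels: int = 2

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; one of {STRUCTURES}")
        if self.n_labels < 2:
            raise ValueError("need at least two labels")


# -- functional pieces (numpy in / numpy out) ----------------------------

def combine_layers(
    Y: np.ndarray, Z: np.ndarray, mask: np.ndarray, structure: str, lam: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Combine the two layer outputs; returns (H, mask_H)."""
    if Y.shape != Z.shape:
        raise ValueError("Y and Z must share a shape")
    mask = np.asarray(mask, dtype=bool)
    if structure == "direct":
        return Z, mask
    if structure == "weighted_sum":
        return lam * Y + (1.0 - lam) * Z, mask
    if structure == "concat_time":
        return np.concatenate([Y, Z], axis=0), np.concatenate([mask, mask])
    if structure == "concat_vector":
        return np.concatenate([Y, Z], axis=1), mask
    raise ValueError(f"unknown structure {structure!r}")


def max_pool_time(H: np.ndarray, mask_H: np.ndarray) -> np.ndarray:
    """Per-dimension maximum over the valid time steps."""
    mask_H = np.asarray(mask_H, dtype=bool)
    if not mask_H.any():
        raise ValueError("max-pooling requires at least one valid row")
    return H[mask_H].max(axis=0)


def apply_hint(h: np.ndarray, x_k: np.ndarray, use_hint: bool) -> np.ndarray:
    """xi = [h, x_k] when the hint layer is on; h unchanged otherwise."""
    if not use_hint:
        return h
    return np.concatenate([h, x_k])


def classify(v: np.ndarray, head: "WSDHead") -> np.ndarray:
    """Probability vector over the K sense labels for one context vector."""
    logits = head.logits_batch(Tensor(v[None]))
    return softmax(logits, axis=-1).data[0]


# -- trainable head ------------------------------------------------------

class WSDHead:
    """Trainable combination + pooling + dense(256)/dense(64)/softmax head."""

    def __init__(self, input_dim: int, cfg: HeadConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        pooled = 2 * input_dim if cfg.structure == "concat_vector" else input_dim
        self.pooled_dim = pooled
        # raw mixing weight; sigmoid(0) = 0.5 is the neutral initialization
        self.lam_raw = Tensor(np.zeros((1, 1, 1)), requires_grad=True)
        self.dense: list[tuple[Tensor, Tensor]] = []
        self._rng = rng

    def build(self, classifier_input_dim: int) -> None:
        """Create the dense stack once the (hinted) vector width is known."""
        rng = self._rng
        dims = [classifier_input_dim, *self.cfg.dense_sizes, self.cfg.n_labels]
        self.dense = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            s = 1.0 / np.sqrt(d_in)
            W = Tensor(rng.uniform(-s, s, size=(d_in, d_out)), requires_grad=True)
            b = Tensor(np.zeros((1, d_out)), requires_grad=True)
            self.dense.append((W, b))

    @property
    def lam(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.lam_raw.data.ravel()[0])))

    def parameters(self) -> list[Tensor]:
        ps = [W for W, _ in self.dense] + [b for _, b in self.dense]
        if self.cfg.structure == "weighted_sum":
            ps.append(self.lam_raw)
        return ps

    # -- batched graph ops ------------------------------------------------
    def pool_batch(self, Y: Tensor, Z: Tensor, mask: np.ndarray) -> Tensor:
        """Combine + masked max-pool a (B, T, D) pair down to (B, pooled_dim)."""
        structure = self.cfg.structure
        if structure == "direct":
            H, mask_H = Z, mask
        elif structure == "weighted_sum":
            lam = self.lam_raw.sigmoid()
            H, mask_H = lam * Y + (1.0 - lam) * Z, mask
        elif structure == "concat_time":
            H = concat([Y, Z], axis=1)
            mask_H = np.concatenate([mask, mask], axis=1)
        else:  # concat_vector
            H, mask_H = concat([Y, Z], axis=-1), mask
        # push masked rows to -inf so the time max ignores them
        bias = np.where(mask_H[:, :, None], 0.0, _NEG)
        return (H + Tensor(bias)).max(axis=1)

    def logits_batch(self, v: Tensor) -> Tensor:
        if not self.dense:
            self.build(v.shape[-1])
        out = v
        for i, (W, b) in enumerate(self.dense):
            out = out @ W + b
            if i < len(self.dense) - 1:
                out = out.relu()
        return out

    def log_probs_batch(
        self, Y: Tensor, Z: Tensor, mask: np.ndarray, hints: np.ndarray | None
    ) -> Tensor:
        h = self.pool_batch(Y, Z, mask)
        if self.cfg.use_hint:
            if hints is None:
                raise ValueError("hint layer is on but no target embeddings were given")
            h = concat([h, Tensor(hints)], axis=-1)
        return log_softmax(self.logits_batch(h), axis=-1)
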