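"""End-to-end disambiguation model: frozen embeddings -> encoder -> head.

A :class:`WSDModel` owns one context encoder (BiLSTM or self-attention)
and one classification head, maps sense labels ``M<k>`` to class indices
``k-1``, and handles padding/masking when batching variable-length
paragraphs. Pre-trained embeddings are inputs, not parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .attention import AttentionEncoder
from .autograd import Tensor
from .bilstm import BiLSTMEncoder
from .embeddings import EncodedInstance
from .head import HeadConfig, WSDHead

__all__ = ["ModelConfig", "WSDModel", "label_to_index", "index_to_label"]


def label_to_index(label: str) -> int:
    return int(label[1:]) - 1


def index_to_label(idx: int) -> str:
    return f"M{idx + 1}"


@dataclass(frozen=True)
class ModelConfig:
    encoder_type: str = "bilstm"  # "bilstm" | "attention"
    embedding_dim: int = 200
    n_labels: int = 2
    structure: str = "concat_time"
    use_hint: bool = False
    hidden_size: int | None = None  # BiLSTM H per direction; default dim//2
    n_heads: int = 2
    dropout: float = 0.5
    use_pe: bool = True
    input_scale: float = 1.0  # embedding-scale standardization; see training._autoscale
    dense_sizes: tuple[int, int] = (256, 64)
    seed: int = 0

    def __post_init__(self):
        if self.encoder_type not in ("bilstm", "attention"):
            raise ValueError(f"unknown encoder type {self.encoder_type!r}")


class WSDModel:
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.encoder_type == "bilstm":
            hidden = cfg.hidden_size or max(1, cfg.embedding_dim // 2)
            self.encoder = BiLSTMEncoder(
                cfg.embedding_dim, hidden_size=hidden, dropout=cfg.dropout,
                input_scale=cfg.input_scale, rng=rng,
            )
        else:
            self.encoder = AttentionEncoder(
                cfg.embedding_dim, n_heads=cfg.n_heads, use_pe=cfg.use_pe,
                input_scale=cfg.input_scale, rng=rng,
            )
        head_cfg = HeadConfig(
            structure=cfg.structure,
            use_hint=cfg.use_hint,
            dense_sizes=tuple(cfg.dense_sizes),
            n_labels=cfg.n_labels,
        )
        self.head = WSDHead(self.encoder.output_dim, head_cfg, rng=rng)
        # build the dense stack eagerly so parameters() is complete up front
        clf_dim = self.head.pooled_dim + (cfg.embedding_dim if cfg.use_hint else 0)
        self.head.build(clf_dim)

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.head.parameters()

    # -- batching ---------------------------------------------------------
    @staticmethod
    def pad_batch(batch: list[EncodedInstance]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Right-pad a batch to its longest sequence; returns (X, mask, hints)."""
        B = len(batch)
        T = max(e.X.shape[0] for e in batch)
        d = batch[0].X.shape[1]
        X = np.zeros((B, T, d))
        mask = np.zeros((B, T), dtype=bool)
        hints = np.zeros((B, d))
        for i, e in enumerate(batch):
            t = e.X.shape[0]
            X[i, :t] = e.X
            mask[i, :t] = e.mask
            hints[i] = e.target_embedding
        return X, mask, hints

    def log_probs(
        self,
        batch: list[EncodedInstance],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        X, mask, hints = self.pad_batch(batch)
        Y, Z = self.encoder.forward_batch(X, mask, training=training, rng=rng)
        if self.cfg.use_hint:
            # the hint is the target's pre-trained embedding, standardized by
            # the same factor as the encoder inputs
            return self.head.log_probs_batch(Y, Z, mask, hints * self.cfg.input_scale)
        return self.head.log_probs_batch(Y, Z, mask, None)

    def loss(
        self,
        batch: list[EncodedInstance],
        training: bool = True,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Mean cross-entropy of the batch."""
        lp = self.log_probs(batch, training=training, rng=rng)
        idx = np.array([label_to_index(e.label) for e in batch])
        picked = lp[np.arange(len(batch)), idx]
        return -picked.mean()

    def predict(self, batch: list[EncodedInstance]) -> tuple[list[str], np.ndarray]:
        """Predicted labels and the full probability matrix (B, K)."""
        lp = self.log_probs(batch, training=False).data
        probs = np.exp(lp)
        labels = [index_to_label(i) for i in probs.argmax(axis=1)]
        return labels, probs

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": t.data for i, t in enumerate(self.parameters())}
        cfg_json = json.dumps(asdict(self.cfg))
        np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "WSDModel":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["__config__"]).decode())
            cfg_dict["dense_sizes"] = tuple(cfg_dict["dense_sizes"])
            model = cls(ModelConfig(**cfg_dict))
            for i, t in enumerate(model.parameters()):
                arr = data[f"p{i}"]
                if arr.shape != t.data.shape:
                    raise ValueError("checkpoint does not match the model configuration")
                t.data = arr.copy()
        return model
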