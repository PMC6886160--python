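"""Pre-trained word-embedding tables (word2vec text format).

The table is frozen during training: the models consume the pre-trained
vectors as fixed inputs and only the encoder/head parameters learn.
Out-of-vocabulary tokens map to the all-zero vector and keep their
position, so windows, masks and positional encodings stay aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corpus import Dataset, Instance

__all__ = [
    "EmbeddingTable",
    "EncodedInstance",
    "load_embedding_table",
    "save_embedding_table",
    "encode_instance",
    "filter_covered_words",
]

log = logging.getLogger(__name__)


@dataclass
class EmbeddingTable:
    dim: int
    vectors: dict[str, np.ndarray]

    @property
    def vocab_size(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def get(self, token: str) -> np.ndarray:
        """Vector for `token`; all-zero if out of vocabulary."""
        v = self.vectors.get(token)
        if v is None:
            return np.zeros(self.dim)
        return v


@dataclass
class EncodedInstance:
    """An instance mapped to its input matrix X (T x dim) plus metadata."""

    X: np.ndarray
    mask: np.ndarray  # length-T booleans; False rows of X are zero
    target_index: int
    target_embedding: np.ndarray
    label: str
    doc_id: str
    word_key: str


def load_embedding_table(path) -> EmbeddingTable:
    """Read a word2vec text file: header ``V D`` then ``token v1 ... vD`` lines.

    Duplicate tokens keep the first occurrence; a wrong value count raises
    with the line number.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header, expected 'V D'")
        declared_v, dim = int(header[0]), int(header[1])
        if declared_v == 0:
            raise ValueError(f"{path}: empty vocabulary")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            token, values = parts[0], parts[1:]
            if len(values) != dim:
                raise ValueError(
                    f"{path} line {lineno}: expected {dim} values, got {len(values)}"
                )
            if token not in vectors:
                vectors[token] = np.array([float(v) for v in values])
    if not vectors:
        raise ValueError(f"{path}: no vectors")
    return EmbeddingTable(dim=dim, vectors=vectors)


def save_embedding_table(table: EmbeddingTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{table.vocab_size} {table.dim}\n")
        for token, vec in table.vectors.items():
            fh.write(token + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def _target_embedding(token: str, table: EmbeddingTable) -> np.ndarray:
    if token in table:
        return table.get(token)
    if "_" in token:
        parts = [table.get(p) for p in token.split("_") if p in table]
        if parts:
            return np.mean(parts, axis=0)
    log.warning("target word %r has no embedding; using zero hint vector", token)
    return np.zeros(table.dim)


def encode_instance(inst: Instance, table: EmbeddingTable) -> EncodedInstance:
    """Map tokens to their embedding rows.

    OOV rows are zero but stay in place, so T and the target index never
    change. The hint vector is the target's *pre-trained* embedding (the
    raw table row, not any contextual output); a multi-word OOV target
    falls back to the mean of its in-vocabulary components.
    """
    T = len(inst.tokens)
    X = np.zeros((T, table.dim))
    for i, tok in enumerate(inst.tokens):
        if tok in table:
            X[i] = table.vectors[tok]
    return EncodedInstance(
        X=X,
        mask=np.ones(T, dtype=bool),
        target_index=inst.target_index,
        target_embedding=_target_embedding(inst.tokens[inst.target_index], table),
        label=inst.label,
        doc_id=inst.doc_id,
        word_key=inst.word_key,
    )


def filter_covered_words(datasets: list[Dataset], table: EmbeddingTable) -> list[Dataset]:
    """Keep only words whose key (or every underscore component) has a vector.

    Mirrors the common situation where a handful of corpus words are
    missing from the pre-trained vocabulary and are excluded from
    training and evaluation.
    """
    kept = []
    for ds in datasets:
        key = ds.word_key
        covered = key in table or (
            "_" in key and all(part in table for part in key.split("_"))
        )
        if covered:
            kept.append(ds)
    return kept
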