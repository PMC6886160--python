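"""Sense-annotated paragraph corpora.

Each ambiguous word has one corpus file: a UTF-8 TSV with one record per
line, ``doc_id<TAB>paragraph<TAB>label``. The single occurrence of the
target word inside the paragraph is wrapped as ``<e>...</e>``; sense labels
are opaque symbols ``M1, M2, ...`` shared across all ambiguous words (a
label carries no meaning beyond distinguishing senses of one word).

Tokenization is deliberately simple and reproducible: lowercase,
whitespace split, leading/trailing ASCII punctuation stripped. Multi-token
targets (e.g. ``<e>heart attack</e>``) are joined with an underscore into
a single token so that one position indexes the ambiguous term.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Instance",
    "Dataset",
    "tokenize",
    "read_sense_file",
    "write_sense_file",
    "window_context",
    "merge_datasets",
    "split_dataset",
]

_LABEL_RE = re.compile(r"^M[1-9][0-9]*$")
_TARGET_RE = re.compile(r"<e>(.*?)</e>", flags=re.DOTALL)
_PUNCT = string.punctuation


@dataclass(frozen=True)
class Instance:
    """One annotated paragraph with its ambiguous word marked.

    Attributes
    ----------
    doc_id : opaque record identifier.
    tokens : lowercase token sequence, length ``T >= 1``.
    target_index : 0-based position of the ambiguous word.
    label : sense symbol matching ``M<k>``.
    word_key : canonical surface form of the ambiguous word.
    """

    doc_id: str
    tokens: tuple[str, ...]
    target_index: int
    label: str
    word_key: str

    def __post_init__(self):
        if not self.tokens:
            raise ValueError(f"{self.doc_id}: empty token sequence")
        if not (0 <= self.target_index < len(self.tokens)):
            raise ValueError(f"{self.doc_id}: target_index out of range")
        if not _LABEL_RE.match(self.label):
            raise ValueError(f"{self.doc_id}: bad sense label {self.label!r}")
        if any(t == "" for t in self.tokens):
            raise ValueError(f"{self.doc_id}: empty token")


@dataclass
class Dataset:
    """All instances of one ambiguous word (or ``ALL`` for a merged corpus)."""

    word_key: str
    instances: list[Instance]
    metadata: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted({inst.label for inst in self.instances})

    @property
    def sense_count(self) -> int:
        return len({inst.label for inst in self.instances})

    def __len__(self) -> int:
        return len(self.instances)


def _clean_token(tok: str) -> str:
    return tok.strip(_PUNCT).lower()


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip edge ASCII punctuation."""
    out = []
    for raw in text.split():
        tok = _clean_token(raw)
        if tok:
            out.append(tok)
    return out


def _parse_record(doc_id: str, paragraph: str, label: str, lineno: int) -> Instance:
    hits = _TARGET_RE.findall(paragraph)
    if len(hits) != 1:
        raise ValueError(
            f"line {lineno}: expected exactly one <e>...</e> target, found {len(hits)}"
        )
    if not _LABEL_RE.match(label):
        raise ValueError(f"line {lineno}: sense label {label!r} does not match M<k>")
    target_surface = hits[0]
    target_parts = tokenize(target_surface)
    if not target_parts:
        raise ValueError(f"line {lineno}: empty target span")
    target_token = "_".join(target_parts)

    before, _, after = _TARGET_RE.split(paragraph)
    left = tokenize(before)
    right = tokenize(after)
    tokens = tuple(left + [target_token] + right)
    return Instance(
        doc_id=doc_id,
        tokens=tokens,
        target_index=len(left),
        label=label,
        word_key=target_token,
    )


def read_sense_file(path) -> Dataset:
    """Parse one corpus file into a :class:`Dataset`.

    Raises ``ValueError`` naming the offending line for malformed records
    and for empty files.
    """
    instances: list[Instance] = []
    word_key = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
            inst = _parse_record(parts[0], parts[1], parts[2], lineno)
            if word_key is None:
                word_key = inst.word_key
            instances.append(inst)
    if not instances:
        raise ValueError(f"{path}: no records")
    return Dataset(word_key=word_key, instances=instances)


def write_sense_file(ds: Dataset, path) -> None:
    """Emit the same TSV dialect :func:`read_sense_file` reads."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for inst in ds.instances:
            toks = list(inst.tokens)
            t = inst.target_index
            # restore the target marker; underscores become spaces again
            toks[t] = "<e>" + toks[t].replace("_", " ") + "</e>"
            fh.write(f"{inst.doc_id}\t{' '.join(toks)}\t{inst.label}\n")


def window_context(inst: Instance, half_width: int) -> Instance:
    """Clip an instance to ``half_width`` tokens either side of the target.

    At a paragraph boundary the window is silently truncated; with full
    availability the result has ``2*half_width + 1`` tokens. The target
    token itself is never altered.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    t = inst.target_index
    lo = max(0, t - half_width)
    hi = min(len(inst.tokens), t + half_width + 1)
    return replace(inst, tokens=inst.tokens[lo:hi], target_index=t - lo)


def merge_datasets(datasets: list[Dataset]) -> Dataset:
    """Concatenate word corpora into one universal dataset (``word_key='ALL'``).

    Labels are left untouched: the ``M<k>`` symbols are shared across words
    and carry no cross-word semantics, so no remapping is meaningful.
    """
    if not datasets:
        raise ValueError("merge_datasets needs at least one dataset")
    instances = [inst for ds in datasets for inst in ds.instances]
    return Dataset(word_key="ALL", instances=instances)


def split_dataset(
    ds: Dataset,
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[Dataset, Dataset, Dataset]:
    """Deterministic, label-stratified train/valid/test partition.

    Within every label stratum the valid/test shares get ``floor(f*n)``
    instances and the remainder goes to train, so small per-word corpora
    keep all senses represented in the training set.
    """
    f_train, f_valid, f_test = fractions
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)

    train_idx: list[int] = []
    valid_idx: list[int] = []
    test_idx: list[int] = []
    by_label: dict[str, list[int]] = {}
    for i, inst in enumerate(ds.instances):
        by_label.setdefault(inst.label, []).append(i)
    for label in sorted(by_label):
        idx = np.array(by_label[label])
        rng.shuffle(idx)
        n = len(idx)
        n_valid = int(np.floor(f_valid * n))
        n_test = int(np.floor(f_test * n))
        valid_idx.extend(idx[:n_valid])
        test_idx.extend(idx[n_valid : n_valid + n_test])
        train_idx.extend(idx[n_valid + n_test :])
    if not train_idx:
        raise ValueError("split would leave the training set empty")

    def _sub(indices: list[int]) -> Dataset:
        indices = sorted(indices)
        return Dataset(
            word_key=ds.word_key,
            instances=[ds.instances[i] for i in indices],
        )

    return _sub(train_idx), _sub(valid_idx), _sub(test_idx)
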