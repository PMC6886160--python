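"""Synthetic sense-annotated corpora with controllable separability.

The generator emulates the shape of a benchmark like MSH WSD — one corpus
of ~200 labelled paragraphs per ambiguous word — through a two-pool
mixture model: every (word, sense) pair owns a pool of cue tokens, and
each context token is drawn from that cue pool with probability
``separability`` or from a shared noise pool otherwise. The Bayes-optimal
accuracy is therefore a known, tunable function of ``separability`` and
paragraph length, which gives downstream training tests an oracle.

With ``shared_cue_rotation`` the cue pools are shared by all words but the
pool-to-sense assignment is rotated per word: the same context evidence
then implies different labels for different target words, so a model can
only resolve it by attending to the target word itself. This mimics the
regime where a single universal model benefits from being reminded which
word it is disambiguating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Dataset, Instance
from .embeddings import EmbeddingTable

__all__ = ["SynthSpec", "generate_corpus", "generate_mislabeled_variant"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic corpus generator.

    Defaults follow the benchmark shape: ~200 paragraphs per word, two
    senses, paragraphs of 20-40 tokens, cue probability 0.9.
    """

    n_words: int = 1
    senses_per_word: int = 2
    n_paragraphs: int = 200
    paragraph_len_range: tuple[int, int] = (20, 40)
    vocab_size: int = 500
    dim: int = 16
    separability: float = 0.9
    seed: int = 0
    cue_pool_size: int = 20
    shared_cue_rotation: bool = False

    def __post_init__(self):
        if self.paragraph_len_range[0] < 3:
            raise ValueError("minimum paragraph length must be >= 3")
        if not (0.0 <= self.separability <= 1.0):
            raise ValueError("separability must lie in [0, 1]")
        if self.senses_per_word < 2:
            raise ValueError("need at least two senses per word")


def _build_pools(spec: SynthSpec) -> tuple[list[list[list[str]]], list[str]]:
    """Return per-word, per-sense cue pools and the shared noise pool."""
    n_pools = (
        spec.senses_per_word
        if spec.shared_cue_rotation
        else spec.n_words * spec.senses_per_word
    )
    n_cue = n_pools * spec.cue_pool_size
    n_noise = spec.vocab_size - n_cue
    if n_noise < 1:
        raise ValueError(
            f"vocab_size={spec.vocab_size} too small for {n_pools} cue pools "
            f"of {spec.cue_pool_size} tokens plus a noise pool"
        )
    cue_tokens = [f"c{i:05d}" for i in range(n_cue)]
    noise = [f"n{i:05d}" for i in range(n_noise)]
    flat_pools = [
        cue_tokens[p * spec.cue_pool_size : (p + 1) * spec.cue_pool_size]
        for p in range(n_pools)
    ]
    pools: list[list[list[str]]] = []
    for w in range(spec.n_words):
        if spec.shared_cue_rotation:
            # word w assigns shared pool (s + w) % S to its sense s
            pools.append(
                [flat_pools[(s + w) % spec.senses_per_word] for s in range(spec.senses_per_word)]
            )
        else:
            base = w * spec.senses_per_word
            pools.append([flat_pools[base + s] for s in range(spec.senses_per_word)])
    return pools, noise


def cue_pools(spec: SynthSpec) -> list[list[list[str]]]:
    """Expose the generator's cue pools (word -> sense -> tokens)."""
    return _build_pools(spec)[0]


def generate_corpus(spec: SynthSpec) -> tuple[list[Dataset], EmbeddingTable]:
    """Generate one dataset per ambiguous word plus a matching embedding table.

    Every paragraph contains its ambiguous word exactly once, at a uniform
    position; sense labels are balanced within one instance; embedding
    vectors are i.i.d. uniform on ``[-0.5/dim, 0.5/dim]`` (the customary
    word2vec initialization scale). Fully deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pools, noise = _build_pools(spec)
    lo, hi = spec.paragraph_len_range

    datasets: list[Dataset] = []
    for w in range(spec.n_words):
        word = f"ambig{w:03d}"
        # balanced label sequence, within +-1
        counts = [spec.n_paragraphs // spec.senses_per_word] * spec.senses_per_word
        for s in range(spec.n_paragraphs % spec.senses_per_word):
            counts[s] += 1
        senses = np.repeat(np.arange(spec.senses_per_word), counts)
        rng.shuffle(senses)

        instances = []
        for k, s in enumerate(senses):
            L = int(rng.integers(lo, hi + 1))
            pos = int(rng.integers(0, L))
            cue = pools[w][s]
            toks = []
            for j in range(L):
                if j == pos:
                    toks.append(word)
                elif rng.random() < spec.separability:
                    toks.append(cue[int(rng.integers(0, len(cue)))])
                else:
                    toks.append(noise[int(rng.integers(0, len(noise)))])
            instances.append(
                Instance(
                    doc_id=f"{word}_{k:04d}",
                    tokens=tuple(toks),
                    target_index=pos,
                    label=f"M{s + 1}",
                    word_key=word,
                )
            )
        datasets.append(Dataset(word_key=word, instances=instances))

    vocab = (
        [f"ambig{w:03d}" for w in range(spec.n_words)]
        + sorted({t for ps in pools for pool in ps for t in pool})
        + noise
    )
    vecs = rng.uniform(-0.5 / spec.dim, 0.5 / spec.dim, size=(len(vocab), spec.dim))
    table = EmbeddingTable(dim=spec.dim, vectors={t: vecs[i] for i, t in enumerate(vocab)})
    return datasets, table


def generate_mislabeled_variant(ds: Dataset, flip_fraction: float, seed: int) -> Dataset:
    """Flip ``floor(flip_fraction * N)`` labels to a different valid label.

    The flipped doc_ids are recorded in ``metadata['flipped_doc_ids']`` so
    consensus-error reports can be checked against the ground truth.
    """
    if not (0.0 <= flip_fraction < 0.5):
        raise ValueError("flip_fraction must lie in [0, 0.5)")
    labels = ds.labels
    if len(labels) < 2:
        raise ValueError("need at least two senses to flip labels")
    rng = np.random.default_rng(seed)
    n_flip = int(np.floor(flip_fraction * len(ds.instances)))
    flip_idx = set(rng.choice(len(ds.instances), size=n_flip, replace=False).tolist())

    out = []
    flipped_ids = []
    for i, inst in enumerate(ds.instances):
        if i in flip_idx:
            alternatives = [lab for lab in labels if lab != inst.label]
            new_label = alternatives[int(rng.integers(0, len(alternatives)))]
            out.append(
                Instance(
                    doc_id=inst.doc_id,
                    tokens=inst.tokens,
                    target_index=inst.target_index,
                    label=new_label,
                    word_key=inst.word_key,
                )
            )
            flipped_ids.append(inst.doc_id)
        else:
            out.append(inst)
    return Dataset(
        word_key=ds.word_key,
        instances=out,
        metadata={**ds.metadata, "flipped_doc_ids": flipped_ids},
    )
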