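"""Canned synthetic-benchmark experiments.

These are the package's headline studies at desk scale, shared by the
test suite, the reproduction script and the examples. Each experiment
generates its corpus with the :mod:`medwsd.synthetic` generator, runs the
models end to end and reports plain test accuracies. Problem sizes are
kept small (16-dimensional embeddings, hidden size 16, one or ten words)
so a full run takes minutes on one CPU; the methods note discusses what
these scaled-down conditions do and do not show.
"""

from __future__ import annotations

import numpy as np

from .baselines import naive_bayes_accuracy
from .corpus import split_dataset
from .model import ModelConfig
from .synthetic import SynthSpec, generate_corpus, generate_mislabeled_variant
from .training import (
    TrainConfig,
    consensus_error_report,
    encode_dataset,
    ensemble_vote,
    evaluate,
    train_universal,
    train_word_specific,
)

__all__ = ["sense_recovery", "universal_hint", "ensemble_consensus"]

ENCODERS = ("bilstm", "attention")
STRUCTURES = ("direct", "weighted_sum", "concat_time", "concat_vector")


def sense_recovery(seed: int = 0) -> dict[str, float]:
    """Word-specific training across all encoder x structure configurations.

    One synthetic word, two senses, 200 paragraphs of 20-40 tokens at
    separability 0.9, embeddings of dimension 16; models use hidden size
    16 (BiLSTM) / two heads (attention), the 25-25 window, a 70/10/20
    split and at most 50 epochs with patience-5 early stopping. Returns
    ``{"<encoder>/<structure>": test_accuracy}`` plus the unigram
    Naive-Bayes reference under ``"naive_bayes"``.
    """
    spec = SynthSpec(seed=seed)
    datasets, table = generate_corpus(spec)
    tc = TrainConfig(
        batch_size=16, max_epochs=50, window_half_width=25,
        seed=seed, split_seed=seed,
    )
    out: dict[str, float] = {}
    for enc in ENCODERS:
        for st in STRUCTURES:
            mc = ModelConfig(
                encoder_type=enc, hidden_size=16, n_heads=2, structure=st, seed=seed
            )
            _, reports = train_word_specific(datasets, table, mc, tc)
            out[f"{enc}/{st}"] = reports[datasets[0].word_key].test_accuracy

    tr, _, te = split_dataset(datasets[0], tc.split_fractions, tc.split_seed)
    out["naive_bayes"] = naive_bayes_accuracy(tr, te)
    return out


def universal_hint(seed: int = 0, seeds_per_arm: int = 3) -> dict:
    """Universal training with and without the target-word hint layer.

    Ten synthetic words share rotated cue pools (`shared_cue_rotation`),
    so the context under-determines the label unless the model keys on
    the target word — the regime in which concatenating the target
    embedding to the pooled context vector should pay off. Each arm is
    trained with `seeds_per_arm` seeds; means are compared.
    """
    spec = SynthSpec(
        n_words=10, n_paragraphs=60, seed=seed, shared_cue_rotation=True
    )
    datasets, table = generate_corpus(spec)
    result: dict = {"hint_on": [], "hint_off": []}
    for hint in (True, False):
        for s in range(seeds_per_arm):
            run_seed = seed + s
            tc = TrainConfig(
                batch_size=16, max_epochs=30, patience=8,
                window_half_width=25, seed=run_seed, split_seed=run_seed,
            )
            mc = ModelConfig(
                encoder_type="bilstm", hidden_size=16, structure="concat_time",
                use_hint=hint, seed=run_seed,
            )
            _, report = train_universal(datasets, table, mc, tc)
            result["hint_on" if hint else "hint_off"].append(report.test_accuracy)
    result["hint_on_mean"] = float(np.mean(result["hint_on"]))
    result["hint_off_mean"] = float(np.mean(result["hint_off"]))
    return result


def ensemble_consensus(seed: int = 0, flip_fraction: float = 0.03) -> dict:
    """Four-structure ensemble voting plus the consensus-error report.

    Trains the four attention-encoder structures on one perfectly
    separable word, then evaluates them against a test set whose labels
    were flipped on ``flip_fraction`` of instances. Reports majority- and
    weighted-vote accuracies and the unanimous-wrong-answer (consensus
    error) count, whose instances should be exactly the flipped ones when
    every model has converged.
    """
    spec = SynthSpec(separability=1.0, seed=seed)
    datasets, table = generate_corpus(spec)
    ds = datasets[0]
    tc = TrainConfig(
        batch_size=16, max_epochs=50, window_half_width=25, seed=seed, split_seed=seed
    )
    tr, va, te = split_dataset(ds, tc.split_fractions, tc.split_seed)
    te_flipped = generate_mislabeled_variant(te, flip_fraction, seed=seed + 1)
    test_e = encode_dataset(te_flipped, table, tc.window_half_width)

    pred_maps: list[dict[str, str]] = []
    val_accs: list[float] = []
    for st in STRUCTURES:
        mc = ModelConfig(encoder_type="attention", n_heads=2, structure=st, seed=seed)
        models, reports = train_word_specific([ds], table, mc, tc)
        model = models[ds.word_key]
        rep = reports[ds.word_key]
        val_accs.append(rep.valid_accuracies[rep.best_epoch - 1] if rep.valid_accuracies else 1.0)
        _, preds = evaluate(model, test_e)
        pred_maps.append({d: p["pred"] for d, p in preds.items()})

    gold = {inst.doc_id: inst.label for inst in te_flipped.instances}

    def acc(pm: dict[str, str]) -> float:
        return float(np.mean([pm[d] == gold[d] for d in gold]))

    majority = ensemble_vote(pred_maps, val_accuracies=val_accs)
    weighted = ensemble_vote(pred_maps, weights=[max(a, 1e-6) for a in val_accs])
    report = consensus_error_report(pred_maps, te_flipped)
    flipped = set(te_flipped.metadata["flipped_doc_ids"])
    return {
        "per_structure_accuracy": [acc(pm) for pm in pred_maps],
        "majority_vote_accuracy": acc(majority),
        "weighted_vote_accuracy": acc(weighted),
        "consensus_error_count": report["count"],
        "consensus_error_fraction": report["fraction"],
        "consensus_within_flipped": set(report["doc_ids"]) <= flipped,
        "n_flipped": len(flipped),
        "n_test": len(gold),
    }
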