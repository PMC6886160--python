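"""Training loops, evaluation, ensembles and the consensus-error report.

Optimization follows the regime the disambiguation models were designed
for: Adagrad with an exponentially decayed learning rate (start 0.05,
staircase decay by 0.96 every 2500 optimizer steps) and checkpoint-restore
early stopping — save parameters whenever a new minimum validation loss
appears, stop once the validation loss has not improved for `patience`
consecutive epochs, and restore the best checkpoint before testing. When
no validation set exists (the 90/10 regime) training runs a fixed number
of epochs instead.

Two regimes are provided: *word-specific* (one independent model per
ambiguous word) and *universal* (a single model on the merged corpus,
where the hint layer is on by default — re-emphasizing the target word is
what makes one shared model viable, while for word-specific models the
hint is redundant and off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .attention import pe_matched_scale
from .corpus import Dataset, merge_datasets, split_dataset, window_context
from .embeddings import EmbeddingTable, EncodedInstance, encode_instance
from .model import ModelConfig, WSDModel

__all__ = [
    "TrainConfig",
    "TrainReport",
    "Adagrad",
    "EarlyStopper",
    "lr_at",
    "encode_dataset",
    "train_model",
    "train_word_specific",
    "train_universal",
    "evaluate",
    "ensemble_vote",
    "consensus_error_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.05
    decay_every: int = 2500
    decay_base: float = 0.96
    patience: int = 5
    max_epochs: int = 200
    fixed_epochs: int = 50  # used when there is no validation set
    batch_size: int = 32
    seed: int = 0
    window_half_width: int | None = 25  # None = whole paragraph
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    split_seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0.0 < self.decay_base < 1.0):
            raise ValueError("decay_base must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainReport:
    word_key: str
    train_losses: list[float] = field(default_factory=list)
    valid_losses: list[float] = field(default_factory=list)
    valid_accuracies: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    epochs_run: int = 0
    steps_taken: int = 0
    test_accuracy: float | None = None
    restored_checkpoint: bool = False


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Staircase schedule: lr0 * base^floor(step / decay_every)."""
    return cfg.lr0 * cfg.decay_base ** (step // cfg.decay_every)


class Adagrad:
    """Per-parameter accumulated squared gradients divide each update.

    Accumulators start at 0.1 (the TensorFlow convention), which bounds
    the very first steps and keeps later updates from being starved by a
    single large initial gradient.
    """

    def __init__(self, params, eps: float = 1e-8, initial_accumulator: float = 0.1):
        self.params = list(params)
        self.accum = [np.full_like(p.data, initial_accumulator) for p in self.params]
        self.eps = eps

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        for p, acc in zip(self.params, self.accum):
            if p.grad is None:
                continue
            acc += p.grad**2
            p.data -= lr * p.grad / (np.sqrt(acc) + self.eps)


class EarlyStopper:
    """Min-validation-loss checkpointing with epoch patience."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch: int | None = None
        self._since_best = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record an epoch's validation loss; returns True on improvement."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self._since_best = 0
            return True
        self._since_best += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self._since_best >= self.patience


def encode_dataset(
    ds: Dataset, table: EmbeddingTable, half_width: int | None = None
) -> list[EncodedInstance]:
    """Window (optionally) and embed every instance of a dataset."""
    out = []
    for inst in ds.instances:
        if half_width is not None:
            inst = window_context(inst, half_width)
        out.append(encode_instance(inst, table))
    return out


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _eval_loss_acc(model: WSDModel, data: list[EncodedInstance], batch_size: int):
    losses = []
    correct = 0
    for i in range(0, len(data), batch_size):
        batch = data[i : i + batch_size]
        lp = model.log_probs(batch, training=False)
        idx = [int(e.label[1:]) - 1 for e in batch]
        losses.append(float(-lp.data[np.arange(len(batch)), idx].mean()) * len(batch))
        correct += int((lp.data.argmax(axis=1) == np.array(idx)).sum())
    return sum(losses) / len(data), correct / len(data)


def train_model(
    model: WSDModel,
    train_set: list[EncodedInstance],
    valid_set: list[EncodedInstance],
    cfg: TrainConfig,
) -> TrainReport:
    """Fit one model; returns the per-epoch trace (without test accuracy)."""
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adagrad(model.parameters())
    stopper = EarlyStopper(cfg.patience)
    report = TrainReport(word_key="")
    checkpoint: list[np.ndarray] | None = None
    step = 0
    n_epochs = cfg.max_epochs if valid_set else cfg.fixed_epochs

    for epoch in range(1, n_epochs + 1):
        epoch_losses = []
        for idx in _batches(len(train_set), cfg.batch_size, rng):
            batch = [train_set[i] for i in idx]
            opt.zero_grad()
            loss = model.loss(batch, training=True, rng=rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at step {step}")
            loss.backward()
            opt.step(lr_at(step, cfg))
            step += 1
            epoch_losses.append(float(loss.data))
        report.train_losses.append(float(np.mean(epoch_losses)))
        report.epochs_run = epoch
        report.steps_taken = step

        if valid_set:
            val_loss, val_acc = _eval_loss_acc(model, valid_set, cfg.batch_size)
            report.valid_losses.append(val_loss)
            report.valid_accuracies.append(val_acc)
            if stopper.update(epoch, val_loss):
                checkpoint = [p.data.copy() for p in model.parameters()]
            if stopper.should_stop:
                break

    if valid_set and checkpoint is not None:
        for p, saved in zip(model.parameters(), checkpoint):
            p.data = saved
        report.best_epoch = stopper.best_epoch
        report.restored_checkpoint = True
    return report


def evaluate(model: WSDModel, data: list[EncodedInstance], batch_size: int = 64):
    """Plain accuracy plus per-instance predictions keyed by doc_id."""
    if not data:
        raise ValueError("cannot evaluate on an empty dataset")
    predictions: dict[str, dict] = {}
    correct = 0
    for i in range(0, len(data), batch_size):
        batch = data[i : i + batch_size]
        labels, probs = model.predict(batch)
        for e, pred, p in zip(batch, labels, probs):
            predictions[e.doc_id] = {"gold": e.label, "pred": pred, "probs": p}
            correct += int(pred == e.label)
    return correct / len(data), predictions


def _autoscale(model_cfg: ModelConfig, table: EmbeddingTable) -> ModelConfig:
    """Standardize the frozen embeddings' scale for the encoder.

    Pre-trained tables arrive at arbitrary magnitudes. When the config
    leaves ``input_scale`` at its neutral 1.0, the training regimes set
    it so the inputs have unit RMS (BiLSTM: keeps initial gate
    pre-activations in the nonlinearities' sensitive range) or the
    positional encoding's RMS (attention: keeps content and position
    contributions commensurate).
    """
    if model_cfg.input_scale != 1.0:
        return model_cfg
    vecs = np.stack(list(table.vectors.values()))
    if model_cfg.encoder_type == "attention":
        return replace(model_cfg, input_scale=pe_matched_scale(vecs))
    rms = float(np.sqrt(np.mean(np.square(vecs))))
    return replace(model_cfg, input_scale=1.0 / rms if rms > 0 else 1.0)


def _split_encode(ds: Dataset, table: EmbeddingTable, cfg: TrainConfig):
    tr, va, te = split_dataset(ds, cfg.split_fractions, cfg.split_seed)
    hw = cfg.window_half_width
    return (
        encode_dataset(tr, table, hw),
        encode_dataset(va, table, hw),
        encode_dataset(te, table, hw),
    )


def train_word_specific(
    datasets: list[Dataset],
    table: EmbeddingTable,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
) -> tuple[dict[str, WSDModel], dict[str, TrainReport]]:
    """One independent model per ambiguous word.

    Datasets with a single observed sense are skipped with a warning. The
    macro-average accuracy is the mean of the per-word test accuracies.
    """
    models: dict[str, WSDModel] = {}
    reports: dict[str, TrainReport] = {}
    for ds in datasets:
        if ds.sense_count < 2:
            log.warning("skipping %r: only one sense observed", ds.word_key)
            continue
        train_e, valid_e, test_e = _split_encode(ds, table, cfg)
        mc = replace(
            _autoscale(model_cfg, table),
            embedding_dim=table.dim,
            n_labels=max(int(l[1:]) for l in ds.labels),
        )
        model = WSDModel(mc)
        report = train_model(model, train_e, valid_e, cfg)
        report.word_key = ds.word_key
        if test_e:
            report.test_accuracy, _ = evaluate(model, test_e)
        models[ds.word_key] = model
        reports[ds.word_key] = report
    return models, reports


def macro_average(reports: dict[str, TrainReport]) -> float:
    accs = [r.test_accuracy for r in reports.values() if r.test_accuracy is not None]
    return float(np.mean(accs)) if accs else float("nan")


def train_universal(
    datasets: list[Dataset],
    table: EmbeddingTable,
    model_cfg: ModelConfig | None = None,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[WSDModel, TrainReport]:
    """A single model on the merged corpus of all words.

    The label space is the maximum sense count over the merged words (the
    ``M<k>`` symbols are shared and carry no cross-word meaning). The hint
    layer defaults to on in this regime.
    """
    merged = merge_datasets(datasets)
    n_labels = max(int(l[1:]) for l in merged.labels)
    if model_cfg is None:
        model_cfg = ModelConfig(use_hint=True)
    model_cfg = replace(
        _autoscale(model_cfg, table), embedding_dim=table.dim, n_labels=n_labels
    )
    train_e, valid_e, test_e = _split_encode(merged, table, cfg)
    model = WSDModel(model_cfg)
    report = train_model(model, train_e, valid_e, cfg)
    report.word_key = "ALL"
    if test_e:
        report.test_accuracy, _ = evaluate(model, test_e)
    return model, report


# -- ensembles -----------------------------------------------------------

def ensemble_vote(
    predictions: list[dict[str, str]],
    weights: list[float] | None = None,
    val_accuracies: list[float] | None = None,
) -> dict[str, str]:
    """Combine per-model prediction maps by (weighted) voting.

    Unweighted voting is a plurality over models; weighted voting sums the
    per-model weights behind each label. Ties go to the label chosen by
    the highest-weight model — or, unweighted, by the model with the best
    validation accuracy (falling back to input order).
    """
    if not predictions:
        raise ValueError("need at least one prediction map")
    doc_ids = set(predictions[0])
    for pm in predictions[1:]:
        if set(pm) != doc_ids:
            raise ValueError("prediction maps cover different doc_id sets")
    if weights is not None:
        if len(weights) != len(predictions) or any(w <= 0 for w in weights):
            raise ValueError("weights must be positive, one per model")
        rank = list(weights)
    elif val_accuracies is not None:
        rank = list(val_accuracies)
    else:
        rank = [0.0] * len(predictions)
    # tie-break owner: the highest-ranked model (ties by input order)
    boss = max(range(len(predictions)), key=lambda i: (rank[i], -i))

    out: dict[str, str] = {}
    for doc in doc_ids:
        score: dict[str, float] = {}
        for i, pm in enumerate(predictions):
            w = weights[i] if weights is not None else 1.0
            score[pm[doc]] = score.get(pm[doc], 0.0) + w
        best = max(score.values())
        tied = [lab for lab, s in score.items() if s == best]
        out[doc] = tied[0] if len(tied) == 1 else (
            predictions[boss][doc] if predictions[boss][doc] in tied else sorted(tied)[0]
        )
    return out


def consensus_error_report(
    predictions: list[dict[str, str]], truth: Dataset
) -> dict:
    """Instances on which *every* model agrees on the same wrong label.

    These unanimous errors are the natural candidates for annotation
    problems and bound the accuracy achievable on the corpus.
    """
    if not predictions:
        raise ValueError("need at least one prediction map")
    gold = {inst.doc_id: inst.label for inst in truth.instances}
    missing = set(gold) - set(predictions[0])
    if missing or set(predictions[0]) - set(gold):
        raise ValueError("prediction maps and truth cover different doc_ids")
    doc_ids = []
    for doc, true_label in gold.items():
        votes = {pm[doc] for pm in predictions}
        if len(votes) == 1 and next(iter(votes)) != true_label:
            doc_ids.append(doc)
    doc_ids.sort()
    return {
        "doc_ids": doc_ids,
        "count": len(doc_ids),
        "fraction": len(doc_ids) / len(gold) if gold else 0.0,
    }
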