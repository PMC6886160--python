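"""Optimization schedule, early stopping, evaluation and ensembles."""

import numpy as np
import pytest

from medwsd import (
    EarlyStopper,
    ModelConfig,
    SynthSpec,
    TrainConfig,
    WSDModel,
    consensus_error_report,
    encode_dataset,
    ensemble_vote,
    evaluate,
    generate_corpus,
    lr_at,
    train_model,
    train_universal,
    train_word_specific,
)
from medwsd.corpus import Dataset, Instance
from medwsd.training import Adagrad, macro_average


class TestLrSchedule:
    @pytest.mark.parametrize(
        "step,expected",
        [(0, 0.05), (1, 0.05), (2499, 0.05), (2500, 0.048), (5000, 0.04608)],
    )
    def test_staircase_values(self, step, expected):
        assert lr_at(step, TrainConfig()) == pytest.approx(expected)


class TestEarlyStopper:
    def test_reference_loss_sequence_stops_after_epoch_seven(self):
        losses = [1.0, 0.9, 0.95, 0.96, 0.94, 0.97, 0.98, 0.99]
        stopper = EarlyStopper(patience=5)
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            stopper.update(epoch, loss)
            if stopper.should_stop:
                stopped_at = epoch
                break
        assert stopper.best_epoch == 2
        assert stopped_at == 7

    def test_monotone_improvement_never_stops(self):
        stopper = EarlyStopper(patience=5)
        for epoch in range(1, 51):
            assert stopper.update(epoch, 1.0 / epoch)
            assert not stopper.should_stop
        assert stopper.best_epoch == 50


class TestAdagrad:
    def test_accumulated_squares_shrink_the_step(self):
        from medwsd.autograd import Tensor

        p = Tensor(np.zeros(1), requires_grad=True)
        opt = Adagrad([p], initial_accumulator=0.0)
        p.grad = np.array([2.0])
        opt.step(lr=1.0)
        first = -p.data[0]  # 1.0 * 2 / sqrt(4) = 1.0
        p.grad = np.array([2.0])
        opt.step(lr=1.0)
        second = -p.data[0] - first  # 2 / sqrt(8)
        assert first == pytest.approx(1.0, abs=1e-6)
        assert second == pytest.approx(2.0 / np.sqrt(8.0), abs=1e-6)
        assert second < first

    def test_default_accumulator_bounds_the_first_step(self):
        from medwsd.autograd import Tensor

        p = Tensor(np.zeros(1), requires_grad=True)
        opt = Adagrad([p])  # accumulators start at 0.1
        p.grad = np.array([2.0])
        opt.step(lr=1.0)
        assert -p.data[0] == pytest.approx(2.0 / np.sqrt(4.1), abs=1e-6)


@pytest.fixture(scope="module")
def tiny_training_setup():
    spec = SynthSpec(
        n_paragraphs=40, paragraph_len_range=(8, 12), vocab_size=120, dim=8,
        separability=1.0, seed=13,
    )
    datasets, table = generate_corpus(spec)
    return datasets, table


class TestTrainModel:
    @staticmethod
    def encoded(datasets, table, n=None):
        enc = encode_dataset(datasets[0], table)
        return enc[:n] if n else enc

    def test_fixed_epoch_regime_without_validation(self, tiny_training_setup):
        datasets, table = tiny_training_setup
        model = WSDModel(ModelConfig(embedding_dim=8, hidden_size=4, seed=0))
        cfg = TrainConfig(fixed_epochs=3, batch_size=8, seed=0)
        report = train_model(model, self.encoded(datasets, table, 24), [], cfg)
        assert report.epochs_run == 3
        assert not report.restored_checkpoint
        assert report.valid_losses == []

    def test_training_is_seed_reproducible(self, tiny_training_setup):
        datasets, table = tiny_training_setup
        reports = []
        for _ in range(2):
            model = WSDModel(ModelConfig(embedding_dim=8, hidden_size=4, seed=3))
            cfg = TrainConfig(fixed_epochs=2, batch_size=8, seed=3)
            reports.append(train_model(model, self.encoded(datasets, table, 24), [], cfg))
        assert reports[0].train_losses == reports[1].train_losses

    def test_empty_training_set_raises(self):
        model = WSDModel(ModelConfig(embedding_dim=8, hidden_size=4))
        with pytest.raises(ValueError):
            train_model(model, [], [], TrainConfig())

    def test_word_specific_macro_average_and_skip(self, tiny_training_setup):
        datasets, table = tiny_training_setup
        mono = Dataset("mono", [i for i in datasets[0].instances if i.label == "M1"])
        cfg = TrainConfig(
            batch_size=8, max_epochs=2, window_half_width=None, split_seed=1, seed=1
        )
        mc = ModelConfig(hidden_size=4, seed=1)
        models, reports = train_word_specific([*datasets, mono], table, mc, cfg)
        assert set(reports) == {d.word_key for d in datasets}  # mono skipped
        accs = [r.test_accuracy for r in reports.values()]
        assert macro_average(reports) == pytest.approx(float(np.mean(accs)))

    def test_single_word_universal_reduces_to_word_specific_shape(self, tiny_training_setup):
        datasets, table = tiny_training_setup
        cfg = TrainConfig(batch_size=8, max_epochs=2, window_half_width=None, seed=2, split_seed=2)
        model, report = train_universal(
            datasets, table, ModelConfig(hidden_size=4, use_hint=True, seed=2), cfg
        )
        assert report.word_key == "ALL"
        assert model.cfg.use_hint
        assert report.test_accuracy is not None


class TestEvaluate:
    def test_accuracy_matches_hand_tally(self, tiny_training_setup):
        datasets, table = tiny_training_setup
        enc = encode_dataset(datasets[0], table)[:10]
        model = WSDModel(ModelConfig(embedding_dim=8, hidden_size=4, seed=5))
        acc, preds = evaluate(model, enc)
        tally = sum(1 for e in enc if preds[e.doc_id]["pred"] == e.label)
        assert acc == pytest.approx(tally / 10)
        assert set(preds) == {e.doc_id for e in enc}

    def test_empty_dataset_raises(self):
        model = WSDModel(ModelConfig(embedding_dim=8, hidden_size=4))
        with pytest.raises(ValueError):
            evaluate(model, [])


class TestEnsembleVote:
    def test_weighted_vote_example(self):
        preds = [{"d": lab} for lab in ("M1", "M1", "M2", "M2")]
        out = ensemble_vote(preds, weights=[1, 1, 1, 2])
        assert out["d"] == "M2"

    def test_unanimous_vote_ignores_weights(self):
        preds = [{"d": "M3"}] * 4
        assert ensemble_vote(preds, weights=[5, 1, 1, 1])["d"] == "M3"

    def test_majority_vote(self):
        preds = [{"d": lab} for lab in ("M1", "M2", "M1", "M1")]
        assert ensemble_vote(preds)["d"] == "M1"

    def test_tie_goes_to_best_validation_model(self):
        preds = [{"d": "M1"}, {"d": "M2"}]
        assert ensemble_vote(preds, val_accuracies=[0.6, 0.9])["d"] == "M2"
        assert ensemble_vote(preds, val_accuracies=[0.9, 0.6])["d"] == "M1"

    def test_random_case_matches_brute_force_tally(self, rng):
        labels = ["M1", "M2", "M3"]
        docs = [f"d{i}" for i in range(20)]
        preds = [{d: labels[rng.integers(0, 3)] for d in docs} for _ in range(4)]
        weights = [float(w) for w in rng.uniform(0.1, 2.0, size=4)]
        out = ensemble_vote(preds, weights=weights)
        for d in docs:
            tally = {}
            for pm, w in zip(preds, weights):
                tally[pm[d]] = tally.get(pm[d], 0.0) + w
            best = max(tally.values())
            winners = {lab for lab, s in tally.items() if s == best}
            assert out[d] in winners

    def test_inconsistent_doc_ids_raise(self):
        with pytest.raises(ValueError):
            ensemble_vote([{"a": "M1"}, {"b": "M1"}])


class TestConsensusErrors:
    @staticmethod
    def truth(n):
        return Dataset(
            "w", [Instance(f"d{i}", ("x", "w", "y"), 1, "M1", "w") for i in range(n)]
        )

    def test_all_correct_gives_empty_report(self):
        preds = [{f"d{i}": "M1" for i in range(10)}] * 3
        rep = consensus_error_report(preds, self.truth(10))
        assert rep == {"doc_ids": [], "count": 0, "fraction": 0.0}

    def test_unanimous_wrong_on_three_percent(self):
        wrong = {"d0", "d1", "d2"}
        preds = [
            {f"d{i}": ("M2" if f"d{i}" in wrong else "M1") for i in range(100)}
            for _ in range(4)
        ]
        rep = consensus_error_report(preds, self.truth(100))
        assert rep["count"] == 3
        assert rep["fraction"] == pytest.approx(0.03)
        assert set(rep["doc_ids"]) == wrong

    def test_disagreement_is_not_consensus(self):
        preds = [{"d0": "M2"}, {"d0": "M3"}]
        rep = consensus_error_report(preds, self.truth(1))
        assert rep["count"] == 0

    def test_mismatched_ids_raise(self):
        with pytest.raises(ValueError):
            consensus_error_report([{"zzz": "M1"}], self.truth(1))
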