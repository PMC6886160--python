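"""Word-specific training: one model per ambiguous word.

Trains a small BiLSTM model with the time-concatenation structure on each
of two synthetic words and prints per-word and macro-average accuracy.
Takes about a minute on one CPU.
"""

from medwsd import ModelConfig, SynthSpec, TrainConfig, generate_corpus, train_word_specific
from medwsd.training import macro_average

spec = SynthSpec(n_words=2, n_paragraphs=100, seed=5)
datasets, table = generate_corpus(spec)

model_cfg = ModelConfig(encoder_type="bilstm", hidden_size=16, structure="concat_time", seed=0)
train_cfg = TrainConfig(batch_size=16, max_epochs=25, window_half_width=25, seed=0, split_seed=0)

models, reports = train_word_specific(datasets, table, model_cfg, train_cfg)
for word, rep in reports.items():
    print(
        f"{word}: {rep.epochs_run} epochs (best {rep.best_epoch}), "
        f"test accuracy {rep.test_accuracy:.3f}"
    )
print(f"macro-average accuracy: {macro_average(reports):.3f}")
# Each word gets its own 70/10/20 split; early stopping restores the
# checkpoint with the lowest validation loss before the test evaluation.
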