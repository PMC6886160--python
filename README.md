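# medwsd

Supervised **word sense disambiguation (WSD)** for biomedical text: given a
paragraph containing one marked ambiguous term (*cold*, *CRF*, *nursing*, ...)
and a fixed inventory of senses `M1, M2, ...`, predict the sense the context
supports. The package is aimed at biomedical NLP practitioners who want a
self-contained, dependency-light reference implementation of deep contextual
WSD models — including a synthetic corpus generator with *controllable* sense
separability, so everything is testable without any external corpus or
pre-trained embedding download.

## The models

Both systems read a paragraph as pre-trained word embeddings
`X = (x_1, ..., x_T)` (frozen; out-of-vocabulary tokens map to zero vectors in
place) and share the same upper layer; only the context encoder differs.

**Encoders** (each a stack of two layers with outputs `Y` and `Z`, both `T × D`):

* *BiLSTM* — two bidirectional LSTM layers with inter-layer dropout. Each
  direction applies the gated recurrence
  `i_t = σ(W_xi x_t + W_hi h_{t−1} + b_i)`, `f_t` and `o_t` analogously,
  `c_t = f_t ⊙ c_{t−1} + i_t ⊙ tanh(W_xc x_t + W_hc h_{t−1} + b_c)`,
  `h_t = o_t ⊙ tanh(c_t)`, and the two directions' states are concatenated
  per step (`D = 2H`).
* *Self-attention* — two identical Transformer-style encoder layers:
  multi-head scaled dot-product attention `Softmax(QKᵀ/√d_k)V` with
  `d_q = d_k = d_v = d_model/h`, a position-wise feed-forward network
  `max(0, zW_1 + b_1)W_2 + b_2` with `d_model × d_model` weights, post-norm
  residuals `LayerNorm(X + Sublayer(X))`, and sinusoidal positional encoding
  added once before layer 1 (`D = d_model`).

**Upper layer** — the outputs `Y`, `Z` are combined by one of four structures:

| structure       | `H`                 | shape   |
|-----------------|---------------------|---------|
| `direct`        | `Z`                 | `T × D` |
| `weighted_sum`  | `λY + (1−λ)Z`       | `T × D` |
| `concat_time`   | `[Y; Z]` over time  | `2T × D`|
| `concat_vector` | `[Y, Z]` per vector | `T × 2D`|

then max-pooled over time to a context vector `h` (`λ ∈ [0,1]` is trainable).
Optionally the target word's own embedding `x_k` is concatenated as a *hint*,
`ξ = [h, x_k]`, before two dense ReLU layers (256, 64) and a softmax over the
sense labels.

**Training** — Adagrad, learning rate 0.05 decayed by 0.96 every 2500 steps
(staircase), checkpoint-restore early stopping on validation loss (patience
5), 70/10/20 stratified splits (or 90/10 with a fixed 50-epoch budget).
Models are trained either *word-specifically* (one per ambiguous word) or
*universally* (one model on the merged corpus, where the hint layer is what
makes a single shared model work). Four-structure ensembles vote (majority or
validation-weighted), and a consensus-error report lists instances where all
models agree on the same wrong label — a probe for annotation noise.

The networks run on a small numpy reverse-mode autodiff engine included in
the package (`medwsd.autograd`), verified by finite-difference checks.

## Worked example

```python
from medwsd import (ModelConfig, SynthSpec, TrainConfig,
                    generate_corpus, train_word_specific)
from medwsd.training import macro_average

datasets, table = generate_corpus(SynthSpec(n_words=2, n_paragraphs=100, seed=5))
models, reports = train_word_specific(
    datasets, table,
    ModelConfig(encoder_type="bilstm", hidden_size=16, structure="concat_time", seed=0),
    TrainConfig(batch_size=16, max_epochs=25, window_half_width=25, seed=0, split_seed=0),
)
for word, rep in reports.items():
    print(f"{word}: {rep.epochs_run} epochs (best {rep.best_epoch}), "
          f"test accuracy {rep.test_accuracy:.3f}")
print(f"macro-average accuracy: {macro_average(reports):.3f}")
```

prints

```
ambig000: 25 epochs (best 25), test accuracy 1.000
ambig001: 25 epochs (best 25), test accuracy 1.000
macro-average accuracy: 1.000
```

i.e. each synthetic word gets its own model and 70/10/20 split; the test
accuracy is the fraction of held-out paragraphs whose sense was recovered,
and the macro-average is the mean over words. The `examples/` directory
walks through every capability (corpus I/O, the generator, both encoders,
word-specific and universal training, ensembles) as short narrative scripts;
a thin `medwsd` CLI (`synthesize`, `train`, `evaluate`, `ensemble`,
`report`) drives the same pipeline from the shell.

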