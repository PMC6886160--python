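# Methods

## Task and data model

The package solves supervised word sense disambiguation (WSD) for
biomedical text: each *instance* is one paragraph with exactly one marked
ambiguous term and a sense label from an opaque per-word inventory
`M1, M2, ...`. Labels are shared symbols across words — `M1` for *cold* and
`M1` for *CRF* have nothing in common — which is what allows a single
*universal* model over the merged corpus of all words. Corpora follow an
MSH-WSD-like shape: one file per ambiguous word, on the order of 200
labelled paragraphs each.

Because no standard serialization exists for such corpora, the package
defines a minimal TSV dialect (`doc_id TAB paragraph TAB label`, with the
target wrapped in `<e>...</e>`). Tokenization is deliberately plain —
lowercase, whitespace split, edge punctuation stripped, multi-word targets
joined with underscores — chosen for reproducibility over linguistic
fidelity; sentence splitting and abbreviation expansion are out of scope.

## Encoders

Both encoders are stacks of exactly two layers and expose the same
interface: per-layer outputs `Y` (layer 1) and `Z` (layer 2), each `T × D`,
with zeroed rows at padded positions.

**BiLSTM.** The classic gated cell (input/forget/output gates, `tanh`
candidate, `h_t = o_t ⊙ tanh(c_t)`), run in both directions with
independent parameters and concatenated per step, so `D = 2H`. Defaults:
`H = 100` per direction (making `D` match a 200-dimensional embedding
table; the scaled-down studies use `H = 16`), dropout 0.5 applied between
layer 1 and layer 2 only (inverted scaling, training only, no recurrent
dropout), initial states zero, weights uniform `±1/√H`. Padding is handled
by gating: state carries through masked steps unchanged, so the backward
direction consumes exactly the reversed valid subsequence.

**Self-attention.** Two identical post-norm Transformer encoder layers:
multi-head scaled dot-product attention with `d_q = d_k = d_v = d_model/h`,
a position-wise FFN whose two weight matrices are `d_model × d_model`
(deliberately *not* the 4× expansion used elsewhere), residual connections
with `LayerNorm(X + Sublayer(X))` (learned gain/bias, ε = 1e-6), and
sinusoidal positional encoding added once before layer 1. Masked key
columns receive a −1e30 additive score, which underflows to an exactly
zero attention weight after the max-shifted softmax. No dropout inside the
attention stack. Head counts default to 2 for word-specific models and 4
for universal ones.

## Input scale standardization

Pre-trained embeddings are frozen inputs, not parameters, and arrive at an
arbitrary magnitude (the synthetic generator uses the word2vec
initialization scale, uniform `±0.5/dim`, which is tiny). Two failure
modes follow if that scale is taken literally: the unit-amplitude
positional sinusoids drown the content signal in the attention encoder,
and the BiLSTM's initial gate pre-activations sit so close to zero that
gradients are minuscule. The training regimes therefore standardize the
input scale per embedding table (`training._autoscale`): inputs to the
BiLSTM are scaled to unit RMS, inputs to the attention encoder to the
positional encoding's RMS (`1/√2`), and the hint vector by the same factor
as its encoder's inputs. This is a deterministic per-table constant, not a
learned quantity; for realistically scaled tables (RMS near 1) it is close
to a no-op. It can be overridden through `ModelConfig.input_scale`.

## Upper layer

The four combination structures are `H = Z` (direct), `H = λY + (1−λ)Z`
(weighted sum, λ kept in [0,1] by storing an unconstrained scalar squashed
through a logistic, initialized at 0.5), time concatenation (`2T × D`) and
vector concatenation (`T × 2D`). Max-pooling takes the per-dimension
maximum over valid rows only, giving a context vector of length `D` (or
`2D` for vector concatenation); pooling a time concatenation is provably
the elementwise max of the two layers' pools, which the tests assert.

The optional *hint* concatenates the target word's raw pre-trained
embedding to the pooled vector, `ξ = [h, x_k]`, before the classifier —
never a contextual output, so that a universal model gets an unambiguous
statement of *which* word it is disambiguating even after pooling has
mixed the sequence. A multi-word target that is itself out of vocabulary
falls back to the mean of its in-vocabulary components. The classifier is
dense 256 → ReLU → 64 → ReLU → K → softmax; ReLU and the uniform
`±1/√fan_in` initialization are unstated in the source design and chosen
as standard.

## Optimization

Adagrad with learning rate `0.05 · 0.96^⌊step/2500⌋` (staircase; a "step"
is one batch update). Accumulators start at 0.1 — the TensorFlow
convention — rather than 0: with zero-initialized accumulators the very
first gradient fully normalizes itself (an effective sign-step of size
lr), and a single large initial gradient then starves all later updates,
which made training outcomes depend visibly on the seed. Early stopping
monitors validation *loss*: a checkpoint is saved at each new minimum and
training stops after `patience = 5` epochs without improvement, restoring
the best checkpoint before testing. ("Loss" is the self-consistent reading
where the stopping metric and the checkpoint metric agree.) Without a
validation set (the 90/10 regime) training runs a fixed 50 epochs with no
restore. Splits are stratified by label within each word — with ~200
paragraphs per word an unstratified 10% validation set is too unstable —
with `floor(f·n)` per stratum to valid/test and the remainder to train.
Batch sizes default to 32 (universal) and 16 (word-specific). Divergent
(non-finite) losses abort with a diagnostic rather than continuing.

## Synthetic corpus generator

Each (word, sense) pair owns a disjoint pool of cue tokens; every context
token is drawn from the sense's cue pool with probability `separability`,
otherwise from a shared noise pool, and the ambiguous word itself appears
exactly once at a uniform position. Labels are balanced within one
instance; paragraph lengths are uniform on a range (default 20–40);
embeddings are i.i.d. uniform `±0.5/dim`. Everything is a deterministic
function of the spec's seed, byte for byte. A unigram Naive-Bayes
classifier is Bayes-adjacent for this mixture, so `separability` gives a
known accuracy dial: ~chance at 0, essentially perfect at 1 for paragraphs
of ≥20 tokens.

With `shared_cue_rotation` the cue pools are shared across words but the
pool→sense assignment is rotated per word, so the same context evidence
implies different labels for different target words. This is the regime
that motivates the hint layer: a pooled context alone cannot resolve the
label, and the word-identity information that max-pooling tends to wash
out must be re-injected. The generator does *not* attempt linguistic
realism: no grammar, no Zipfian frequencies, no sense imbalance, no
cross-sense cue overlap. Passing results on it demonstrate that the
architecture and training loop can extract a planted contextual signal at
a known difficulty — not performance on real biomedical text.

A `generate_mislabeled_variant` helper flips `⌊fraction·N⌋` labels and
records which, to exercise the consensus-error report: on separable data
with converged models, the instances where *all* models agree on the same
"wrong" label should be exactly the flipped ones, which is the logic of
using unanimous errors to estimate a benchmark's annotation-noise ceiling.

## Study conditions at desk scale

The canned experiments (`medwsd.experiments`) run deliberately small
problems so a full reproduction takes minutes on one CPU: 16-dimensional
embeddings, hidden size 16 / two heads, one word × 200 paragraphs at
separability 0.9 for the per-structure sense-recovery study (70/10/20
split, ≤50 epochs), ten words × 60 paragraphs with rotated shared pools
for the universal hint comparison (three seeds per arm, ≤30 epochs,
patience 8), and a perfectly separable word with 3% flipped test labels
for the ensemble/consensus study (attention encoder, all four
structures). Model-capacity and corpus-size choices scale the original
regime down; the qualitative contrasts (all structures recover senses;
hint ≥ no-hint for universal models; consensus errors ⊆ flips) are the
reproduction targets, not any absolute benchmark number.

## Known limitations

* The autodiff engine is eager and allocation-heavy; it is sized for the
  desk-scale studies, not for 200-dimensional models over 37k paragraphs.
* Frozen embeddings: no fine-tuning path exists, by design.
* OOV tokens are zero vectors kept in place; no subword fallback.
* The universal regime does not rebalance words with unequal instance
  counts.
* Ensemble tie-breaking needs an owner (highest weight or best validation
  accuracy); with neither supplied it falls back to input order.
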