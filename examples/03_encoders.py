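"""The two context encoders side by side on one paragraph.

Encodes a single synthetic paragraph with the two-layer BiLSTM and the
two-layer self-attention encoder, then pools each with the four upper
structures to show the resulting context-vector widths.
"""

import numpy as np

from medwsd import SynthSpec, encode_instance, generate_corpus
from medwsd.attention import AttentionEncoder, encode_attention
from medwsd.bilstm import BiLSTMEncoder, encode_bilstm
from medwsd.head import STRUCTURES, combine_layers, max_pool_time

spec = SynthSpec(n_paragraphs=4, seed=3)
(ds,), table = generate_corpus(spec)
enc = encode_instance(ds.instances[0], table)
T, d = enc.X.shape
print(f"paragraph of T={T} tokens, embedding dim {d}, target at {enc.target_index}")

rng = np.random.default_rng(0)
bilstm = BiLSTMEncoder(d, hidden_size=8, rng=rng)
out_b = encode_bilstm(enc.X, enc.mask, bilstm)
print(f"BiLSTM     : Y {out_b.Y.shape}  Z {out_b.Z.shape}  (D = 2 x hidden)")

attn = AttentionEncoder(d, n_heads=2, rng=rng)
out_a = encode_attention(enc.X, enc.mask, attn)
print(f"attention  : Y {out_a.Y.shape}  Z {out_a.Z.shape}  (D = d_model)")

for structure in STRUCTURES:
    H, mask_H = combine_layers(out_b.Y, out_b.Z, out_b.mask, structure)
    h = max_pool_time(H, mask_H)
    print(f"structure {structure:13s}: H {H.shape} -> pooled h of length {len(h)}")
# direct/weighted_sum/concat_time pool to length D; concat_vector to 2D.
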