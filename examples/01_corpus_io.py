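"""Reading sense-annotated paragraphs, windowing and splitting.

Builds a five-paragraph corpus file for the ambiguous word "cold" in the
package's TSV dialect, parses it, clips a 2-token context window around
the target, and makes a stratified 70/10/20 split.
"""

import tempfile
from pathlib import Path

from medwsd import read_sense_file, split_dataset, window_context

LINES = [
    "d1\tthe <e>cold</e> virus spread quickly through the ward\tM1",
    "d2\ta bitter <e>cold</e> wind blew in from the north\tM2",
    "d3\tshe caught a <e>cold</e> after the long flight\tM1",
    "d4\tthe <e>cold</e> front reached the coast overnight\tM2",
    "d5\tsymptoms of the common <e>cold</e> include coughing\tM1",
]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cold.tsv"
    path.write_text("\n".join(LINES) + "\n")
    ds = read_sense_file(path)

print(f"word={ds.word_key!r}  instances={len(ds)}  senses={ds.labels}")
inst = ds.instances[0]
print(f"first instance: tokens={inst.tokens} target_index={inst.target_index}")

win = window_context(inst, half_width=2)
print(f"2-token window: {win.tokens} (target now at {win.target_index})")
# The window keeps at most 2 tokens either side of the marked word.

train, valid, test = split_dataset(ds, (0.7, 0.1, 0.2), seed=0)
print(f"split sizes: train={len(train)} valid={len(valid)} test={len(test)}")
# Small strata: floor(f*n) per label goes to valid/test, remainder to train.
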