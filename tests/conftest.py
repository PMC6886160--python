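import numpy as np
import pytest

from medwsd import EmbeddingTable, SynthSpec, generate_corpus


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_table():
    """Deterministic 6-token embedding table of dimension 4."""
    rng = np.random.default_rng(7)
    tokens = ["the", "cold", "virus", "spread", "heart", "attack"]
    return EmbeddingTable(
        dim=4, vectors={t: rng.normal(size=4) for t in tokens}
    )


@pytest.fixture()
def corpus_file(tmp_path):
    """A five-record sense file in the TSV dialect."""
    lines = [
        "d1\tthe <e>cold</e> virus spread\tM1",
        "d2\ta bitter <e>cold</e> wind blew outside\tM2",
        "d3\tcaught a <e>cold</e> last week\tM1",
        "d4\tthe <e>cold</e> war era\tM2",
        "d5\tsymptoms of the common <e>cold</e>\tM1",
    ]
    path = tmp_path / "cold.tsv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def small_synth():
    """Two synthetic words, 40 paragraphs each, plus their embedding table."""
    spec = SynthSpec(
        n_words=2, n_paragraphs=40, paragraph_len_range=(10, 20),
        vocab_size=200, dim=8, separability=0.9, seed=5,
    )
    return generate_corpus(spec)
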