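"""Reference classifiers used as accuracy oracles.

A unigram multinomial Naive Bayes over bag-of-token counts is (close to)
Bayes-optimal for the synthetic two-pool mixture corpora, so it anchors
what any sequence model should achieve on separable data.
"""

from __future__ import annotations

from sklearn.feature_extraction.text import CountVectorizer
from sklearn.naive_bayes import MultinomialNB
from sklearn.pipeline import make_pipeline

from .corpus import Dataset

__all__ = ["naive_bayes_accuracy"]


def naive_bayes_accuracy(train: Dataset, test: Dataset) -> float:
    """Fit unigram NB on `train`, return accuracy on `test`."""

    def docs(ds: Dataset):
        return [" ".join(inst.tokens) for inst in ds.instances]

    def labels(ds: Dataset):
        return [inst.label for inst in ds.instances]

    clf = make_pipeline(
        CountVectorizer(tokenizer=str.split, preprocessor=None, lowercase=False, token_pattern=None),
        MultinomialNB(alpha=1.0),
    )
    clf.fit(docs(train), labels(train))
    return float(clf.score(docs(test), labels(test)))
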