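"""Four-label emotion classification behind a pluggable contract.

Every document receives exactly one of {joy, optimism, sadness, anger}.
The shipped backend is a multinomial naive-count lexicon model (add-one
smoothing, uniform class prior) trained on labeled documents; an external
transformer classifier can be plugged in behind the same contract.  Labels
map to a polarity sign: joy/optimism positive, sadness/anger negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from sklearn.naive_bayes import MultinomialNB

from .corpus_io import TokenizedDoc

__all__ = [
    "LABELS",
    "POLARITY",
    "EmotionLabel",
    "EmotionClassifier",
    "BaselineEmotionClassifier",
    "train_baseline",
    "classify_corpus",
]

#: Fixed label order (alphabetical); also the tie-breaking order.
LABELS = ("anger", "joy", "optimism", "sadness")

#: joy/optimism are positive, sadness/anger negative.
POLARITY = {"anger": -1, "joy": +1, "optimism": +1, "sadness": -1}


@dataclass(frozen=True)
class EmotionLabel:
    value: str

    def __post_init__(self) -> None:
        if self.value not in LABELS:
            raise ValueError(f"unknown emotion label: {self.value!r}")

    @property
    def polarity(self) -> int:
        return POLARITY[self.value]


class EmotionClassifier(Protocol):
    """Contract: deterministic map token list -> (label, 4-score vector)."""

    name: str

    def classify(self, tokens: Sequence[str]) -> tuple[EmotionLabel, np.ndarray]: ...


class BaselineEmotionClassifier:
    """Multinomial naive-count lexicon model with add-one smoothing.

    Class priors are uniform, so classification is driven purely by
    per-label token likelihoods.  Tokens unseen in training are ignored; an
    empty (or fully out-of-vocabulary) document scores uniformly and the
    tie breaks to the first label in the fixed alphabetical order.
    """

    def __init__(self, nb: MultinomialNB, vocab_index: dict[str, int]):
        self.name = "baseline-multinomial"
        self._nb = nb
        self._vocab_index = vocab_index

    def _vectorize(self, tokens: Sequence[str]) -> np.ndarray:
        x = np.zeros((1, len(self._vocab_index)))
        for t in tokens:
            j = self._vocab_index.get(t)
            if j is not None:
                x[0, j] += 1.0
        return x

    def classify(self, tokens: Sequence[str]) -> tuple[EmotionLabel, np.ndarray]:
        x = self._vectorize(tokens)
        scores = self._nb.predict_proba(x)[0]
        # classes_ are alphabetical, matching LABELS; first-argmax realizes
        # the fixed tie-break order
        label = LABELS[int(np.argmax(scores))]
        return EmotionLabel(label), scores


def train_baseline(
    docs: Sequence[TokenizedDoc] | Sequence[Sequence[str]],
    labels: Sequence[str],
) -> BaselineEmotionClassifier:
    """Fit the lexicon baseline on labeled documents.

    Requires at least one document per emotion label.
    """
    token_lists = [d.tokens if isinstance(d, TokenizedDoc) else d for d in docs]
    if len(token_lists) != len(labels):
        raise ValueError("docs and labels must have equal length")
    present = set(labels)
    missing = [lb for lb in LABELS if lb not in present]
    if missing:
        raise ValueError(f"missing label classes in training data: {missing}")
    vocab = sorted({t for toks in token_lists for t in toks})
    vocab_index = {t: j for j, t in enumerate(vocab)}
    X = np.zeros((len(token_lists), len(vocab)))
    for i, toks in enumerate(token_lists):
        for t in toks:
            X[i, vocab_index[t]] += 1.0
    nb = MultinomialNB(alpha=1.0, fit_prior=False)
    nb.fit(X, np.asarray(labels, dtype=object))
    assert list(nb.classes_) == list(LABELS)
    return BaselineEmotionClassifier(nb, vocab_index)


def classify_corpus(
    docs: Sequence[TokenizedDoc],
    classifier: EmotionClassifier,
) -> tuple[list[EmotionLabel], np.ndarray]:
    """Classify every document; returns labels plus a D x 4 score matrix."""
    labels: list[EmotionLabel] = []
    scores = np.empty((len(docs), len(LABELS)))
    for i, doc in enumerate(docs):
        try:
            label, sc = classifier.classify(doc.tokens)
        except Exception as exc:  # pragma: no cover - adapter failure path
            raise RuntimeError(f"classifier failed on document {doc.id!r}") from exc
        labels.append(label)
        scores[i] = sc
    return labels, scores
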