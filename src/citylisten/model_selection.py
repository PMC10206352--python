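"""Topic-count selection, term ranking and topic pruning.

Coherence follows the C_V construction: word co-occurrence is counted in
boolean sliding windows over the corpus, each top word of a topic gets a
vector of NPMI values against the topic's top-word set, and the topic score
averages the cosine similarity between each word vector and the set-sum
vector (one-set segmentation).  Candidate topic counts are scored by
refitting from scratch and the argmax is selected.

Term ranking uses the relevance interpolation
``r(w, t) = lambda * log phi_tw + (1 - lambda) * log(phi_tw / p_w)``
between within-topic probability (lambda = 1) and lift (lambda = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import TokenizedDoc, Vocabulary
from .lda_gibbs import TopicModel, fit_lda

__all__ = [
    "WindowCounts",
    "CoherenceReport",
    "RelevanceRanking",
    "TopicSummary",
    "count_windows",
    "npmi",
    "coherence_cv",
    "sweep_k",
    "corpus_word_probabilities",
    "relevance_rank",
    "prune_topics",
]

DEFAULT_WINDOW = 110
DEFAULT_EPSILON = 1e-12


@dataclass
class WindowCounts:
    """Boolean sliding-window occurrence counts for a fixed word set."""

    n_windows: int
    counts: dict[str, int]
    pair_counts: dict[frozenset, int]

    def count(self, w: str) -> int:
        return self.counts.get(w, 0)

    def pair_count(self, wi: str, wj: str) -> int:
        if wi == wj:
            return self.count(wi)
        return self.pair_counts.get(frozenset((wi, wj)), 0)


def count_windows(
    docs_tokens: Sequence[Sequence[str]],
    words: Sequence[str],
    window: int = DEFAULT_WINDOW,
) -> WindowCounts:
    """Count windows containing each word / unordered word pair.

    A sliding boolean window of ``window`` tokens moves over each document;
    documents shorter than the window contribute a single window.
    """
    word_set = set(words)
    n_windows = 0
    counts: dict[str, int] = {w: 0 for w in word_set}
    pair_counts: dict[frozenset, int] = {}
    for tokens in docs_tokens:
        n = len(tokens)
        if n == 0:
            continue
        spans = [(0, n)] if n <= window else [(i, i + window) for i in range(n - window + 1)]
        for lo, hi in spans:
            present = word_set.intersection(tokens[lo:hi])
            n_windows += 1
            for w in present:
                counts[w] += 1
            present_l = sorted(present)
            for a in range(len(present_l)):
                for b in range(a + 1, len(present_l)):
                    key = frozenset((present_l[a], present_l[b]))
                    pair_counts[key] = pair_counts.get(key, 0) + 1
    return WindowCounts(n_windows=n_windows, counts=counts, pair_counts=pair_counts)


def npmi(
    word_i: str,
    word_j: str,
    counts: WindowCounts,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Normalized pointwise mutual information of two words, in [-1, 1].

    Words that never co-occur floor at -1; a word never observed at all
    yields 0 with a warning.
    """
    n = counts.n_windows
    ci, cj = counts.count(word_i), counts.count(word_j)
    if n == 0 or ci == 0 or cj == 0:
        warnings.warn(
            f"word never observed in any window: {word_i if ci == 0 else word_j!r}",
            stacklevel=2,
        )
        return 0.0
    cij = counts.pair_count(word_i, word_j)
    if cij == 0:
        return -1.0
    p_i, p_j, p_ij = ci / n, cj / n, cij / n
    if p_ij >= 1.0:
        return 1.0
    num = np.log(max(p_ij, epsilon) / max(p_i * p_j, epsilon))
    den = -np.log(max(p_ij, epsilon))
    return float(max(-1.0, min(1.0, num / den)))


def _top_words(model: TopicModel, topic: int, top_n: int) -> list[str]:
    phi_row = model.phi_hat[topic]
    # ties broken lexicographically via secondary sort on the token string
    tokens = model.vocab.tokens
    order = sorted(range(len(tokens)), key=lambda i: (-phi_row[i], tokens[i]))
    # restrict to words with genuinely positive (non-floor) probability mass
    positive = [i for i in order if phi_row[i] > 0]
    if len(positive) < top_n:
        warnings.warn(
            f"topic {topic} has only {len(positive)} positive-probability words",
            stacklevel=2,
        )
    return [tokens[i] for i in positive[:top_n]]


def coherence_cv(
    model: TopicModel,
    corpus: Sequence[TokenizedDoc],
    top_n: int = 10,
    window: int = DEFAULT_WINDOW,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """C_V-style coherence of a fitted model over a reference corpus."""
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    topic_words = [_top_words(model, t, top_n) for t in range(model.k)]
    all_words = sorted({w for ws in topic_words for w in ws})
    counts = count_windows([d.tokens for d in corpus], all_words, window)
    scores = []
    for words in topic_words:
        m = len(words)
        if m < 2:
            continue
        mat = np.empty((m, m))
        for a in range(m):
            for b in range(m):
                mat[a, b] = npmi(words[a], words[b], counts, epsilon)
        v_set = mat.sum(axis=0)
        sims = []
        for a in range(m):
            sims.append(_cosine(mat[a], v_set))
        scores.append(float(np.mean(sims)))
    return float(np.mean(scores)) if scores else float("nan")


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class CoherenceReport:
    """Coherence per candidate topic count and the selected k."""

    candidates: list[tuple[int, float]]
    selected_k: int
    top_n: int
    window: int


def sweep_k(
    corpus: Sequence[TokenizedDoc],
    k_grid: Sequence[int],
    alpha: float | str = "auto",
    beta: float = 0.01,
    n_iters: int = 200,
    burn_in: int = 100,
    top_n: int = 10,
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
    vocab: Vocabulary | None = None,
) -> CoherenceReport:
    """Fit one model per candidate k and select the coherence argmax.

    Each candidate refits from scratch with a seed derived from
    ``(seed, k)``; there is no warm-starting across candidates.  Ties go to
    the smaller k.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    candidates: list[tuple[int, float]] = []
    for k in k_grid:
        sub_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))
        model, _ = fit_lda(
            corpus,
            k=k,
            alpha=alpha,
            beta=beta,
            n_iters=n_iters,
            burn_in=burn_in,
            seed=sub_seed,
            vocab=vocab,
            compute_ll=False,
        )
        candidates.append((int(k), coherence_cv(model, corpus, top_n=top_n, window=window)))
    best = max(candidates, key=lambda kv: (kv[1], -kv[0]))
    return CoherenceReport(candidates=candidates, selected_k=best[0], top_n=top_n, window=window)


@dataclass
class RelevanceRanking:
    """Relevance-ordered top terms per topic."""

    lambda_: float
    topic_terms: list[list[tuple[str, float]]]  # per topic, descending score
    p_w: np.ndarray  # corpus-wide marginal word probabilities (vocab order)


def corpus_word_probabilities(
    corpus: Sequence[TokenizedDoc], vocab: Vocabulary
) -> np.ndarray:
    """Empirical marginal probability of each vocabulary word."""
    counts = np.zeros(len(vocab), dtype=float)
    for doc in corpus:
        for tok in doc.tokens:
            if tok in vocab:
                counts[vocab.id_of(tok)] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("corpus contains no in-vocabulary tokens")
    return counts / total


def relevance_rank(
    model: TopicModel,
    lambda_: float = 0.6,
    top_n: int = 20,
    p_w: np.ndarray | None = None,
    corpus: Sequence[TokenizedDoc] | None = None,
) -> RelevanceRanking:
    """Rank each topic's terms by relevance at ``lambda_``.

    ``p_w`` may be supplied directly; otherwise it is computed from
    ``corpus``.  Ties in score are broken lexicographically.
    """
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda_ must be in [0, 1]")
    if p_w is None:
        if corpus is None:
            raise ValueError("either p_w or corpus must be given")
        p_w = corpus_word_probabilities(corpus, model.vocab)
    p_w = np.asarray(p_w, dtype=float)
    tokens = model.vocab.tokens
    eps = 1e-300  # guard only; phi_hat and p_w are strictly positive in practice
    log_phi = np.log(np.maximum(model.phi_hat, eps))
    log_lift = log_phi - np.log(np.maximum(p_w, eps))[None, :]
    scores = lambda_ * log_phi + (1.0 - lambda_) * log_lift
    topic_terms = []
    for t in range(model.k):
        order = sorted(range(len(tokens)), key=lambda i: (-scores[t, i], tokens[i]))
        topic_terms.append([(tokens[i], float(scores[t, i])) for i in order[:top_n]])
    return RelevanceRanking(lambda_=lambda_, topic_terms=topic_terms, p_w=p_w)


@dataclass
class TopicSummary:
    topic: int
    share: float
    top_terms: list[str]
    retained: bool


def prune_topics(
    k: int,
    doc_topics: Sequence[int],
    min_share: float = 0.05,
    doc_weights: Sequence[float] | None = None,
    ranking: RelevanceRanking | None = None,
    top_n_terms: int = 10,
) -> list[TopicSummary]:
    """Flag topics whose corpus share falls below ``min_share``.

    ``doc_topics`` are exclusive per-document topic labels (from fusion
    clustering or argmax theta); ``doc_weights`` default to document token
    counts when given, else each document counts once.  Shares sum to 1.
    """
    labels = np.asarray(doc_topics, dtype=int)
    if labels.size == 0:
        raise ValueError("doc_topics must be non-empty")
    w = (
        np.asarray(doc_weights, dtype=float)
        if doc_weights is not None
        else np.ones(labels.size)
    )
    shares = np.zeros(k)
    for t in range(k):
        shares[t] = w[labels == t].sum()
    shares /= w.sum()
    out = []
    for t in range(k):
        terms = [w_ for w_, _ in ranking.topic_terms[t][:top_n_terms]] if ranking else []
        out.append(
            TopicSummary(
                topic=t,
                share=float(shares[t]),
                top_terms=terms,
                retained=bool(shares[t] >= min_share),
            )
        )
    return out
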