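"""Shared fixtures: small handcrafted corpora and the standard synthetic
fixtures used across modules (built once per session)."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import linear_sum_assignment

from citylisten import (
    GeneratorConfig,
    TokenizedDoc,
    build_corpus,
    default_stopwords,
    fit_lda,
    generate_corpus,
)

settings.register_profile(
    "ci", max_examples=50, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TS = datetime(2020, 3, 15, 12, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def stop_kw():
    """Default stopwords plus the query keyword, as the pipeline uses."""
    return frozenset(default_stopwords()) | {"covid"}


@pytest.fixture()
def tiny_docs():
    """Four short documents over two disjoint vocabularies."""
    return [
        TokenizedDoc("a", ("apple", "banana", "apple"), TS, "X"),
        TokenizedDoc("b", ("banana", "apple", "banana"), TS, "X"),
        TokenizedDoc("c", ("carrot", "daikon", "carrot"), TS, "Y"),
        TokenizedDoc("d", ("daikon", "carrot", "daikon"), TS, "Y"),
    ]


def truth_indices(docs):
    """Map kept documents back to generator row indices via their ids."""
    return [int(d.id[1:]) for d in docs]


def mean_phi_tv(model, truth):
    """Mean total-variation distance between fitted and true topic-word
    rows after Hungarian matching, in the true vocabulary space."""
    tok_to_true = {t: i for i, t in enumerate(truth.vocab_tokens)}
    k, Vt = truth.phi_true.shape
    phi_f = np.zeros((model.k, Vt))
    for j, tok in enumerate(model.vocab.tokens):
        if tok in tok_to_true:
            phi_f[:, tok_to_true[tok]] = model.phi_hat[:, j]
    cost = np.zeros((model.k, k))
    for a in range(model.k):
        for b in range(k):
            cost[a, b] = 0.5 * np.abs(phi_f[a] - truth.phi_true[b]).sum()
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def separable_config(seed: int = 11) -> GeneratorConfig:
    """Fully disjoint topic vocabularies, sparse mixtures, no noise/markers."""
    return GeneratorConfig(
        k_true=4, V=500, D=1000, alpha=0.02, block_mass=1.0,
        doc_length_mean=15.0, noise_rate=0.0, marker_rate=0.0, seed=seed,
    )


@pytest.fixture(scope="session")
def separable(stop_kw):
    """Separable synthetic corpus with a fitted k=4 model."""
    records, truth = generate_corpus(separable_config())
    docs, report, vocab = build_corpus(records, stopwords=stop_kw)
    model, trace = fit_lda(
        docs, k=4, n_iters=400, burn_in=200, seed=5, vocab=vocab, compute_ll=True
    )
    true_labels = truth.topic_label[truth_indices(docs)]
    return {
        "records": records,
        "truth": truth,
        "docs": docs,
        "report": report,
        "vocab": vocab,
        "model": model,
        "trace": trace,
        "true_labels": true_labels,
    }


def recovery_config(seed: int) -> GeneratorConfig:
    """The topic-count/parameter recovery conditions: k=4, V=500, D=2000,
    alpha 0.1, disjoint-leaning blocks, mild junk noise, no markers."""
    return GeneratorConfig(
        k_true=4, V=500, D=2000, alpha=0.1, noise_rate=0.05, marker_rate=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_runs(stop_kw):
    """Ten independent recovery corpora with k-sweeps and k=4 refits."""
    from citylisten import sweep_k

    out = []
    for seed in range(10):
        records, truth = generate_corpus(recovery_config(1000 + seed))
        docs, _, vocab = build_corpus(records, stopwords=stop_kw)
        report = sweep_k(
            docs, range(2, 9), n_iters=200, burn_in=100, seed=seed, vocab=vocab
        )
        model, _ = fit_lda(
            docs, k=4, n_iters=400, burn_in=200, seed=seed, vocab=vocab,
            compute_ll=False,
        )
        out.append({"truth": truth, "docs": docs, "report": report, "model": model})
    return out
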