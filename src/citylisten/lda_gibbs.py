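"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The sampler integrates out the topic mixtures theta and topic-word
distributions phi and resamples each token's topic label z from the
closed-form conditional

    p(z = t | rest)  propto  (n_dt + alpha) * (n_tw + beta) / (n_t + V beta)

where the counts exclude the token being resampled.  Point estimates are
posterior means averaged over thinned post-burn-in sweeps.

Documents are canonicalized (sorted by id) before sampling and each document
draws from its own seeded random stream, so the fit is invariant to the
order in which documents are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._gibbs import run_gibbs
from .corpus_io import TokenizedDoc, Vocabulary

__all__ = [
    "TopicModel",
    "FitTrace",
    "gibbs_conditional",
    "fit_lda",
    "infer_theta",
    "save_model",
    "load_model",
]


@dataclass
class TopicModel:
    """A fitted LDA state: smoothed posterior-mean phi and theta."""

    k: int
    alpha: float
    beta: float
    phi_hat: np.ndarray  # k x V, rows sum to 1
    theta_hat: np.ndarray  # D x k, rows sum to 1, in input doc order
    assignments: list[np.ndarray]  # final per-token topic labels per doc
    vocab: Vocabulary
    doc_ids: list[str]
    n_iters: int
    burn_in: int
    seed: int


@dataclass
class FitTrace:
    """Per-sweep collapsed joint log-likelihood, plus optional thinned
    assignment snapshots (token-major, canonical doc order)."""

    log_likelihood: np.ndarray
    z_samples: np.ndarray | None = None
    canonical_tokens: np.ndarray | None = None
    canonical_offsets: np.ndarray | None = None


def gibbs_conditional(
    doc_counts: np.ndarray,
    topic_word_counts: np.ndarray,
    topic_totals: np.ndarray,
    word_id: int,
    alpha: float,
    beta: float,
    V: int,
) -> np.ndarray:
    """The collapsed conditional over topics for one held-out token.

    All count arrays must already exclude the token being resampled.
    """
    doc_counts = np.asarray(doc_counts, dtype=float)
    tw = np.asarray(topic_word_counts, dtype=float)
    totals = np.asarray(topic_totals, dtype=float)
    if tw.ndim == 2:
        tw = tw[:, word_id]
    if np.any(doc_counts < 0) or np.any(tw < 0) or np.any(totals < 0):
        raise ValueError("negative counts: bookkeeping is inconsistent")
    p = (doc_counts + alpha) * (tw + beta) / (totals + V * beta)
    return p / p.sum()


def _canonicalize(
    corpus: Sequence[TokenizedDoc], vocab: Vocabulary | None
) -> tuple[Vocabulary, list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Sort docs by id, encode tokens, and build flat arrays for the kernel.

    Returns (vocab, ids in input order, order permutation, tokens, offsets)
    where ``order[j]`` is the input index of the j-th canonical document.
    """
    if vocab is None:
        vocab = Vocabulary(t for d in corpus for t in d.tokens)
    ids = [d.id for d in corpus]
    order = np.argsort(np.array(ids, dtype=object), kind="stable")
    tokens_per_doc = []
    for j in order:
        enc = vocab.encode(corpus[j].tokens, skip_oov=True)
        tokens_per_doc.append(np.asarray(enc, dtype=np.int32))
    offsets = np.zeros(len(corpus) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(t) for t in tokens_per_doc])
    flat = (
        np.concatenate(tokens_per_doc)
        if offsets[-1] > 0
        else np.empty(0, dtype=np.int32)
    )
    return vocab, ids, order, flat.astype(np.int32), offsets


def _doc_states(seed: int, doc_ids_canonical: Sequence[str]) -> np.ndarray:
    """One xorshift64* state per document, spawned from the master seed and
    the document's position in canonical order."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * len(doc_ids_canonical), dtype=np.uint64)[::2].copy()
    states[states == 0] = np.uint64(0x9E3779B97F4A7C15)
    return states


def fit_lda(
    corpus: Sequence[TokenizedDoc],
    k: int,
    alpha: float | str = "auto",
    beta: float = 0.01,
    n_iters: int = 1000,
    burn_in: int = 500,
    sample_every: int = 10,
    seed: int = 0,
    vocab: Vocabulary | None = None,
    compute_ll: bool = True,
    collect_z: bool = False,
    n_restarts: int = 1,
) -> tuple[TopicModel, FitTrace]:
    """Fit LDA with k topics by collapsed Gibbs sampling.

    ``alpha="auto"`` uses the common symmetric default 50/k; ``beta``
    defaults to 0.01.  Estimates average the smoothed count ratios over
    every ``sample_every``-th post-burn-in sweep.

    ``n_restarts > 1`` runs that many independent chains (seeds derived
    from ``seed``) and keeps the one with the highest mean post-burn-in
    joint log-likelihood — collapsed Gibbs can stall in merged/split topic
    modes on corpora with very unequal topic sizes, and restart selection
    by joint likelihood reliably escapes them.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    if alpha == "auto":
        alpha = 50.0 / k
    alpha = float(alpha)
    if burn_in > n_iters:
        raise ValueError("burn_in cannot exceed n_iters")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    vocab, ids, order, tokens, offsets = _canonicalize(corpus, vocab)
    V = len(vocab)
    n_distinct = len(np.unique(tokens)) if tokens.size else 0
    if k > max(n_distinct, 1):
        warnings.warn(
            f"k={k} exceeds the number of distinct words ({n_distinct}); "
            "some topics will be empty",
            stacklevel=2,
        )

    best = None
    for r in range(n_restarts):
        if r == 0:
            chain_seed = seed  # single-restart behavior is unchanged
        else:
            chain_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(r,)).generate_state(1)[0]
                % (2**31)
            )
        states = _doc_states(chain_seed, [ids[j] for j in order])
        out = run_gibbs(
            tokens,
            offsets,
            states,
            k,
            V,
            alpha,
            float(beta),
            int(n_iters),
            int(burn_in),
            int(sample_every),
            bool(compute_ll or n_restarts > 1),
            bool(collect_z),
        )
        window = max(1, (n_iters - burn_in) or n_iters // 4)
        score = float(out[3][-window:].mean()) if (compute_ll or n_restarts > 1) else 0.0
        if best is None or score > best[0]:
            best = (score, out)
    phi, theta_canon, z_flat, ll, z_samples = best[1]

    # map canonical-order results back to input order
    D = len(corpus)
    theta = np.empty_like(theta_canon)
    assignments: list[np.ndarray] = [np.empty(0, dtype=np.int32)] * D
    for canon_pos, input_idx in enumerate(order):
        theta[input_idx] = theta_canon[canon_pos]
        assignments[input_idx] = z_flat[offsets[canon_pos] : offsets[canon_pos + 1]].copy()

    model = TopicModel(
        k=k,
        alpha=alpha,
        beta=float(beta),
        phi_hat=phi,
        theta_hat=theta,
        assignments=assignments,
        vocab=vocab,
        doc_ids=ids,
        n_iters=n_iters,
        burn_in=burn_in,
        seed=seed,
    )
    trace = FitTrace(
        log_likelihood=ll,
        z_samples=z_samples if collect_z else None,
        canonical_tokens=tokens if collect_z else None,
        canonical_offsets=offsets if collect_z else None,
    )
    return model, trace


def infer_theta(
    model: TopicModel,
    doc: TokenizedDoc,
    n_iters: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Fold-in Gibbs: topic mixture for an unseen document with phi fixed.

    Out-of-vocabulary tokens are skipped; a document with no in-vocabulary
    tokens yields the uniform mixture (with a warning).  Averages the
    smoothed mixture over the second half of the sweeps.
    """
    k, alpha = model.k, model.alpha
    word_ids = np.asarray(model.vocab.encode(doc.tokens, skip_oov=True), dtype=np.int64)
    if word_ids.size == 0:
        warnings.warn(f"document {doc.id!r} has no in-vocabulary tokens", stacklevel=2)
        return np.full(k, 1.0 / k)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    n = word_ids.size
    z = rng.integers(k, size=n)
    n_dt = np.bincount(z, minlength=k).astype(float)
    theta_acc = np.zeros(k)
    n_samples = 0
    burn = n_iters // 2
    phi_cols = model.phi_hat[:, word_ids]  # k x n
    for it in range(n_iters):
        for i in range(n):
            n_dt[z[i]] -= 1
            p = (n_dt + alpha) * phi_cols[:, i]
            p /= p.sum()
            z[i] = rng.choice(k, p=p)
            n_dt[z[i]] += 1
        if it >= burn:
            theta_acc += (n_dt + alpha) / (n + k * alpha)
            n_samples += 1
    theta = theta_acc / n_samples
    return theta / theta.sum()


# ---------------------------------------------------------------------------
# Serialization: a model directory of delimited tables + key-value settings.
# ---------------------------------------------------------------------------


def save_model(model: TopicModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tokens = model.vocab.tokens
    with (out / "phi.tsv").open("w", encoding="utf-8") as fh:
        fh.write("topic\t" + "\t".join(tokens) + "\n")
        for t in range(model.k):
            fh.write(str(t) + "\t" + "\t".join(repr(float(x)) for x in model.phi_hat[t]) + "\n")
    with (out / "theta.tsv").open("w", encoding="utf-8") as fh:
        fh.write("doc_id\t" + "\t".join(f"topic{t}" for t in range(model.k)) + "\n")
        for i, doc_id in enumerate(model.doc_ids):
            fh.write(doc_id + "\t" + "\t".join(repr(float(x)) for x in model.theta_hat[i]) + "\n")
    with (out / "settings.txt").open("w", encoding="utf-8") as fh:
        for key in ("k", "alpha", "beta", "n_iters", "burn_in", "seed"):
            fh.write(f"{key}={getattr(model, key)!r}\n")


def load_model(model_dir: str | Path) -> TopicModel:
    d = Path(model_dir)
    settings = {}
    for line in (d / "settings.txt").read_text("utf-8").splitlines():
        if line.strip():
            key, val = line.split("=", 1)
            settings[key] = eval(val, {"__builtins__": {}})  # noqa: S307 - repr round-trip
    with (d / "phi.tsv").open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        phi_rows = [
            [float(x) for x in line.rstrip("\n").split("\t")[1:]] for line in fh if line.strip()
        ]
    with (d / "theta.tsv").open("r", encoding="utf-8") as fh:
        fh.readline()
        doc_ids, theta_rows = [], []
        for line in fh:
            if line.strip():
                parts = line.rstrip("\n").split("\t")
                doc_ids.append(parts[0])
                theta_rows.append([float(x) for x in parts[1:]])
    vocab = Vocabulary(header)
    # header is already sorted (Vocabulary order), so column order is stable
    return TopicModel(
        k=int(settings["k"]),
        alpha=float(settings["alpha"]),
        beta=float(settings["beta"]),
        phi_hat=np.asarray(phi_rows),
        theta_hat=np.asarray(theta_rows),
        assignments=[],
        vocab=vocab,
        doc_ids=doc_ids,
        n_iters=int(settings["n_iters"]),
        burn_in=int(settings["burn_in"]),
        seed=int(settings["seed"]),
    )
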