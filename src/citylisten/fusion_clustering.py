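"""Fused topic-vector + sentence-embedding clustering.

Each document's LDA topic mixture is concatenated with a sentence embedding,
the fused vectors are compressed through a single-hidden-layer autoencoder,
and K-Means on the latent codes assigns every document to exactly one
topic-cluster.  A Hungarian alignment maps cluster ids back onto LDA topic
ids so cluster output can be reported in topic terms.

The default embedder is a deterministic hashed token-count random
projection; any transformer sentence encoder can be plugged in behind the
same ``SentenceEmbedder`` contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .corpus_io import TokenizedDoc
from .lda_gibbs import TopicModel

__all__ = [
    "SentenceEmbedder",
    "HashedEmbedder",
    "FusedRepresentation",
    "AutoencoderState",
    "ClusterAssignment",
    "embed_corpus",
    "fuse",
    "train_autoencoder",
    "cluster_latent",
    "align_clusters_to_topics",
    "cluster_corpus",
]


@dataclass
class SentenceEmbedder:
    """Contract: a named, deterministic map text -> R^dim."""

    name: str
    dim: int
    embed: Callable[[str], np.ndarray]


class HashedEmbedder:
    """Hashed token-count random projection, deterministic given (dim, seed).

    Every distinct token hashes (blake2b) to a fixed pseudo-random direction
    in R^dim; a text embeds as the L2-normalized sum of its token vectors,
    so texts sharing many tokens have high cosine similarity.  The empty
    text embeds as the zero vector.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.name = f"hashed-{dim}-{seed}"
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            h = hashlib.blake2b(
                token.encode("utf-8"), digest_size=8, key=str(self.seed).encode()
            ).digest()
            rng = np.random.default_rng(int.from_bytes(h, "little"))
            vec = rng.standard_normal(self.dim)
            self._cache[token] = vec
        return vec

    def embed(self, text: str) -> np.ndarray:
        tokens = text.split()
        if not tokens:
            return np.zeros(self.dim)
        out = np.zeros(self.dim)
        for t in tokens:
            out += self._token_vector(t)
        norm = np.linalg.norm(out)
        return out / norm if norm > 0 else out


def embed_corpus(docs: Sequence[TokenizedDoc], embedder) -> np.ndarray:
    """Embed each document's (preprocessed) text; rows follow doc order."""
    rows = []
    for doc in docs:
        try:
            rows.append(np.asarray(embedder.embed(" ".join(doc.tokens)), dtype=float))
        except Exception as exc:  # pragma: no cover - adapter failure path
            raise RuntimeError(f"embedder failed on document {doc.id!r}") from exc
    return np.vstack(rows) if rows else np.empty((0, embedder.dim))


@dataclass
class FusedRepresentation:
    """Concatenated [gamma * topic block, embedding block] rows.

    Both blocks are centered and scaled to unit total variance before
    concatenation so that, at gamma = 1, neither block dominates Euclidean
    distances merely through dimensionality or units; gamma then weights the
    topic block relative to the embedding block (gamma = 0 removes the topic
    signal entirely, large gamma makes it dominate).
    """

    gamma: float
    X: np.ndarray  # D x (k + dim)
    k: int
    dim: int


def fuse(theta_hat: np.ndarray, embeddings: np.ndarray, gamma: float = 1.0) -> FusedRepresentation:
    """Concatenate the gamma-weighted topic block with the standardized
    embedding block (each block normalized to unit total variance)."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    embeddings = np.asarray(embeddings, dtype=float)
    if theta_hat.shape[0] != embeddings.shape[0]:
        raise ValueError(
            f"row count mismatch: theta has {theta_hat.shape[0]} rows, "
            f"embeddings {embeddings.shape[0]}"
        )
    mu = embeddings.mean(axis=0)
    sd = embeddings.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)  # constant columns stay centered at 0
    emb_std = (embeddings - mu) / sd
    if embeddings.shape[1] > 0:
        emb_std = emb_std / np.sqrt(embeddings.shape[1])  # block energy 1
    topic = theta_hat - theta_hat.mean(axis=0)
    energy = np.sqrt(topic.var(axis=0).sum())
    if energy > 1e-12:
        topic = topic / energy  # block energy 1 before gamma
    X = np.hstack([gamma * topic, emb_std])
    if not np.all(np.isfinite(X)):
        raise ValueError("fused representation contains non-finite entries")
    return FusedRepresentation(gamma=float(gamma), X=X, k=theta_hat.shape[1], dim=embeddings.shape[1])


@dataclass
class AutoencoderState:
    """Weights and training record of the dense autoencoder."""

    latent_dim: int
    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    activation: str
    epochs: int
    learning_rate: float
    seed: int
    losses: np.ndarray  # per-epoch reconstruction MSE (post-update)
    final_loss: float

    def encode(self, X: np.ndarray) -> np.ndarray:
        H = np.asarray(X, dtype=float) @ self.W_enc + self.b_enc
        return np.tanh(H) if self.activation == "tanh" else H


def train_autoencoder(
    X: np.ndarray,
    latent_dim: int = 32,
    epochs: int = 500,
    learning_rate: float = 1.0,
    activation: str = "tanh",
    seed: int = 0,
) -> AutoencoderState:
    """Train a one-hidden-layer autoencoder by full-batch gradient descent.

    Encoder: affine map + activation to ``latent_dim``; decoder: affine map
    back.  Minimizes the mean squared reconstruction error over all matrix
    entries; because the gradient carries the 1/(n d) factor of that mean,
    useful learning rates are of order 1 rather than the 1e-3 familiar from
    adaptive optimizers.  Deterministic given the seed.  Raises on
    divergence (non-finite loss).
    """
    if latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    if activation not in ("tanh", "linear"):
        raise ValueError("activation must be 'tanh' or 'linear'")
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    # Glorot-uniform initialization
    lim1 = np.sqrt(6.0 / (d + latent_dim))
    W1 = rng.uniform(-lim1, lim1, size=(d, latent_dim))
    b1 = np.zeros(latent_dim)
    W2 = rng.uniform(-lim1, lim1, size=(latent_dim, d))
    b2 = np.zeros(d)

    losses = np.empty(epochs)
    lr = learning_rate
    for ep in range(epochs):
        A = X @ W1 + b1
        H = np.tanh(A) if activation == "tanh" else A
        Y = H @ W2 + b2
        R = Y - X
        loss = float(np.mean(R * R))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"autoencoder diverged at epoch {ep} (loss non-finite); "
                f"reduce learning_rate={learning_rate}"
            )
        dY = 2.0 * R / R.size
        gW2 = H.T @ dY
        gb2 = dY.sum(axis=0)
        dH = dY @ W2.T
        dA = dH * (1.0 - H * H) if activation == "tanh" else dH
        gW1 = X.T @ dA
        gb1 = dA.sum(axis=0)
        W1 -= lr * gW1
        b1 -= lr * gb1
        W2 -= lr * gW2
        b2 -= lr * gb2
        A = X @ W1 + b1
        H = np.tanh(A) if activation == "tanh" else A
        losses[ep] = float(np.mean((H @ W2 + b2 - X) ** 2))

    return AutoencoderState(
        latent_dim=latent_dim,
        W_enc=W1,
        b_enc=b1,
        W_dec=W2,
        b_dec=b2,
        activation=activation,
        epochs=epochs,
        learning_rate=learning_rate,
        seed=seed,
        losses=losses,
        final_loss=float(losses[-1]) if epochs else float("nan"),
    )


@dataclass
class ClusterAssignment:
    """Exclusive document -> cluster labels plus cluster/topic alignment."""

    labels: np.ndarray  # per-doc cluster id in 0..k-1
    centroids: np.ndarray  # k x latent_dim
    inertia: float
    cluster_to_topic: np.ndarray | None = None

    @property
    def topic_labels(self) -> np.ndarray:
        """Per-doc LDA topic id implied by the cluster alignment."""
        if self.cluster_to_topic is None:
            raise ValueError("clusters have not been aligned to topics")
        return self.cluster_to_topic[self.labels]


def cluster_latent(Z: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> ClusterAssignment:
    """K-Means (k-means++, best of ``n_init`` restarts) on latent codes."""
    Z = np.asarray(Z, dtype=float)
    n_distinct = np.unique(Z, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct rows ({n_distinct})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        tol=1e-6,
        algorithm="lloyd",
        random_state=seed,
    ).fit(Z)
    return ClusterAssignment(
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def align_clusters_to_topics(labels: np.ndarray, theta_hat: np.ndarray) -> np.ndarray:
    """Hungarian assignment of cluster ids to topic ids.

    Maximizes the total per-document topic probability mass
    ``sum_d theta_d[topic(cluster(d))]``; returns ``perm`` with
    ``perm[cluster] = topic`` (a bijection).
    """
    labels = np.asarray(labels, dtype=int)
    theta_hat = np.asarray(theta_hat, dtype=float)
    k = theta_hat.shape[1]
    cost = np.zeros((k, k))
    for c in range(k):
        mask = labels == c
        if mask.any():
            cost[c] = theta_hat[mask].sum(axis=0)
    rows, cols = linear_sum_assignment(-cost)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm


def cluster_corpus(
    model: TopicModel,
    docs: Sequence[TokenizedDoc],
    embedder=None,
    gamma: float = 1.0,
    latent_dim: int = 32,
    epochs: int = 500,
    learning_rate: float = 1.0,
    seed: int = 0,
) -> tuple[ClusterAssignment, AutoencoderState]:
    """End-to-end fusion clustering: embed, fuse, compress, K-Means, align."""
    if embedder is None:
        embedder = HashedEmbedder()
    E = embed_corpus(docs, embedder)
    fused = fuse(model.theta_hat, E, gamma=gamma)
    state = train_autoencoder(
        fused.X,
        latent_dim=min(latent_dim, fused.X.shape[1]),
        epochs=epochs,
        learning_rate=learning_rate,
        seed=seed,
    )
    Z = state.encode(fused.X)
    assignment = cluster_latent(Z, model.k, seed=seed)
    assignment.cluster_to_topic = align_clusters_to_topics(assignment.labels, model.theta_hat)
    return assignment, state
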