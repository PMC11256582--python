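"""DeepWalk node embeddings for the homogeneous drug / target networks.

Truncated uniform random walks turn graph neighborhoods into "sentences";
a skip-gram model trained on those sentences places nodes that co-occur on
walks close together in a d-dimensional space.  The trainer is a compact,
fully vectorized numpy implementation of skip-gram with negative sampling
(SGNS): for every (center, context) pair drawn from a sliding window, the
center vector is pulled toward the context's output vector and pushed away
from a handful of noise nodes drawn from the unigram^0.75 distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .similarity import HomogeneousNetwork

logger = logging.getLogger(__name__)


@dataclass
class WalkCorpus:
    """Random-walk sentences over a network's node indices."""

    walks: list[np.ndarray]
    walk_length: int
    walks_per_node: int
    seed: int
    n_nodes: int
    entity_ids: list[str] = field(default_factory=list)


@dataclass
class EmbeddingMatrix:
    """One d-dimensional vector per entity, rows aligned with entity_ids."""

    entity_ids: list[str]
    vectors: np.ndarray

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, i: int) -> np.ndarray:
        return self.vectors[i]


@dataclass
class DeepWalkParams:
    """Hyperparameters of the walk + skip-gram stage."""

    walks_per_node: int = 10
    walk_length: int = 40
    window: int = 5
    dim: int = 64
    epochs: int = 5
    negative: int = 5
    learning_rate: float = 0.05
    seed: int = 0


def generate_walks(
    net: HomogeneousNetwork,
    walks_per_node: int = 10,
    walk_length: int = 40,
    seed: int = 0,
) -> WalkCorpus:
    """Sample ``walks_per_node`` truncated random walks starting at every
    node.

    Each step moves to a uniformly random neighbor of the current node.
    ``walk_length`` counts nodes, not steps; a walk that reaches an
    isolated node (no neighbors) terminates early, so an isolated start
    node yields the singleton walk ``[node]``.  Runs are deterministic
    for a fixed seed.
    """
    if walks_per_node < 1 or walk_length < 1:
        raise ValueError("walks_per_node and walk_length must be >= 1")
    n = net.n_entities
    if n == 0:
        raise ValueError("empty network")
    neighbors = [np.flatnonzero(net.values[i]) for i in range(n)]
    rng = np.random.default_rng(seed)
    walks: list[np.ndarray] = []
    for _ in range(walks_per_node):
        for start in range(n):
            walk = [start]
            cur = start
            for _ in range(walk_length - 1):
                nbrs = neighbors[cur]
                if nbrs.size == 0:
                    break
                cur = int(nbrs[rng.integers(nbrs.size)])
                walk.append(cur)
            walks.append(np.asarray(walk, dtype=np.int64))
    return WalkCorpus(
        walks=walks,
        walk_length=walk_length,
        walks_per_node=walks_per_node,
        seed=seed,
        n_nodes=n,
        entity_ids=list(net.entity_ids),
    )


def _skipgram_pairs(corpus: WalkCorpus, window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) pairs within the sliding window."""
    centers, contexts = [], []
    for walk in corpus.walks:
        L = walk.size
        if L < 2:
            continue
        for off in range(1, window + 1):
            if off >= L:
                break
            # both directions of the window in one shot
            centers.append(walk[:-off])
            contexts.append(walk[off:])
            centers.append(walk[off:])
            contexts.append(walk[:-off])
    if not centers:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _apply_segment_mean_update(W: np.ndarray, idx: np.ndarray, grads: np.ndarray, lr: float) -> None:
    """W[u] -= lr * mean(grads where idx == u), via sort + reduceat
    (np.add.at is an order of magnitude slower for this access pattern)."""
    order = np.argsort(idx, kind="stable")
    si = idx[order]
    starts = np.flatnonzero(np.r_[True, si[1:] != si[:-1]])
    sums = np.add.reduceat(grads[order], starts, axis=0)
    counts = np.diff(np.r_[starts, si.size])
    W[si[starts]] -= lr * sums / counts[:, None]


def train_skipgram(
    corpus: WalkCorpus,
    dim: int = 64,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.05,
    batch_size: int = 512,
) -> EmbeddingMatrix:
    """Train skip-gram with negative sampling on a walk corpus.

    Nodes that contribute no (center, context) pair — isolated nodes whose
    walks are singletons — receive a zero vector and a warning, so that
    downstream feature concatenation never fails.  Training is
    deterministic for a fixed seed.
    """
    if dim <= 0:
        raise ValueError("dim must be positive")
    if not corpus.walks:
        raise ValueError("empty corpus")
    n = corpus.n_nodes
    centers, contexts = _skipgram_pairs(corpus, window)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((n, dim)) - 0.5) / dim
    W_out = np.zeros((n, dim))

    counts = np.bincount(centers, minlength=n).astype(np.float64)
    missing = np.flatnonzero(counts == 0)
    if centers.size == 0:
        warnings.warn("corpus has no co-occurrence pairs; all embeddings are zero")
        return EmbeddingMatrix(list(corpus.entity_ids), np.zeros((n, dim)))

    noise = counts**0.75
    noise /= noise.sum()

    n_pairs = centers.size
    total_steps = epochs * int(np.ceil(n_pairs / batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            idx = order[lo : lo + batch_size]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(n, size=(idx.size, negative), p=noise)
            lr = learning_rate * max(1.0 - step / total_steps, 1e-4 / learning_rate)
            step += 1

            v_c = W_in[c]                       # (B, d)
            u_pos = W_out[o]                    # (B, d)
            u_neg = W_out[neg]                  # (B, neg, d)

            z_pos = np.clip(np.einsum("bd,bd->b", v_c, u_pos), -30.0, 30.0)
            z_neg = np.clip(np.einsum("bd,bnd->bn", v_c, u_neg), -30.0, 30.0)
            s_pos = 1.0 / (1.0 + np.exp(-z_pos))
            s_neg = 1.0 / (1.0 + np.exp(-z_neg))

            g_pos = (s_pos - 1.0)[:, None]      # positive-pair gradient factor
            g_neg = s_neg[:, :, None]

            grad_c = g_pos * u_pos + np.einsum("bnd->bd", g_neg * u_neg)
            grad_pos = g_pos * v_c
            grad_neg = g_neg * v_c[:, None, :]

            # per-node mean gradient: nodes of a small vocabulary recur many
            # times per batch, and raw per-pair accumulation would overshoot
            _apply_segment_mean_update(W_in, c, grad_c, lr)
            _apply_segment_mean_update(
                W_out,
                np.concatenate([o, neg.ravel()]),
                np.concatenate([grad_pos, grad_neg.reshape(-1, dim)]),
                lr,
            )

    if missing.size:
        warnings.warn(
            f"{missing.size} node(s) never co-occur in the walk corpus; "
            "their embeddings are zero"
        )
        W_in[missing] = 0.0
    return EmbeddingMatrix(list(corpus.entity_ids), W_in)


def embed_network(net: HomogeneousNetwork, params: DeepWalkParams | None = None) -> EmbeddingMatrix:
    """Walks + skip-gram in one call (the DeepWalk pipeline stage)."""
    p = params or DeepWalkParams()
    corpus = generate_walks(net, p.walks_per_node, p.walk_length, seed=p.seed)
    return train_skipgram(
        corpus,
        dim=p.dim,
        window=p.window,
        epochs=p.epochs,
        seed=p.seed,
        negative=p.negative,
        learning_rate=p.learning_rate,
    )
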