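"""The implicit drug-target pair network (DTP graph).

Every (drug, target) combination is a node; two pair nodes are adjacent
iff they share the drug or the target.  For N_D drugs and N_T targets the
graph has N_D * N_T nodes and every node has degree N_D + N_T - 2, so the
adjacency matrix is never materialized: pair ids, adjacency queries,
neighbor enumeration, concatenated pair features and labels are all
computed on demand from O(N_D + N_T) state.

Casting interaction prediction as node classification on this graph lets
an inductive graph network propagate evidence between pairs that share an
endpoint (the same drug tested against other targets, and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingMatrix


@dataclass(frozen=True)
class DTPIndex:
    """Bijection (drug i, target j) <-> pair-node id = i * N_T + j."""

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def __init__(self, drug_ids, target_ids):
        object.__setattr__(self, "drug_ids", tuple(drug_ids))
        object.__setattr__(self, "target_ids", tuple(target_ids))
        if not self.drug_ids or not self.target_ids:
            raise ValueError("need at least one drug and one target")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_pairs(self) -> int:
        """Number of pair nodes, N_D * N_T."""
        return self.n_drugs * self.n_targets

    @property
    def degree(self) -> int:
        """Degree of every pair node: N_D + N_T - 2."""
        return self.n_drugs + self.n_targets - 2

    def pair_id(self, i: int, j: int) -> int:
        if not (0 <= i < self.n_drugs and 0 <= j < self.n_targets):
            raise IndexError(f"pair ({i}, {j}) out of range")
        return i * self.n_targets + j

    def pair_of(self, u: int) -> tuple[int, int]:
        if not 0 <= u < self.n_pairs:
            raise IndexError(f"pair node {u} out of range")
        return divmod(u, self.n_targets)

    def adjacency(self, u: int, v: int) -> int:
        """1 iff the two pair nodes share the drug or the target.

        Literally this rule gives every node a self-loop (u shares both
        endpoints with itself); neighbor enumeration nevertheless
        excludes self, because the layer update of the graph network
        already concatenates the node's own representation.
        """
        iu, ju = self.pair_of(u)
        iv, jv = self.pair_of(v)
        return int(iu == iv or ju == jv)

    def neighbors(self, u: int) -> np.ndarray:
        """All pair nodes sharing the drug or the target with ``u``
        (self excluded): N_T - 1 same-drug + N_D - 1 same-target nodes."""
        i, j = self.pair_of(u)
        nt = self.n_targets
        same_drug = i * nt + np.delete(np.arange(nt), j)
        same_target = np.delete(np.arange(self.n_drugs), i) * nt + j
        return np.concatenate([same_drug, same_target])

    def pair_ids_of(self, pairs) -> np.ndarray:
        arr = np.asarray(pairs, dtype=np.int64)
        return arr[:, 0] * self.n_targets + arr[:, 1]


@dataclass
class DTPLabels:
    """Known-interaction labels: 1 iff the pair is a known interaction."""

    positives: set[tuple[int, int]]

    @classmethod
    def from_edges(cls, index: DTPIndex, edges: list[tuple[str, str]]) -> "DTPLabels":
        """Build labels from (drug_id, target_id) string pairs."""
        drug_pos = {d: i for i, d in enumerate(index.drug_ids)}
        target_pos = {t: j for j, t in enumerate(index.target_ids)}
        positives = set()
        for d, t in edges:
            if d not in drug_pos or t not in target_pos:
                raise KeyError(f"unknown interaction endpoint ({d!r}, {t!r})")
            positives.add((drug_pos[d], target_pos[t]))
        return cls(positives)

    def label(self, i: int, j: int) -> int:
        return int((i, j) in self.positives)

    def n_positives(self) -> int:
        return len(self.positives)

    def n_negatives(self, index: DTPIndex) -> int:
        return index.n_pairs - len(self.positives)

    def positive_node_ids(self, index: DTPIndex) -> np.ndarray:
        for i, j in self.positives:
            index.pair_id(i, j)  # bounds check
        return np.sort(np.asarray(
            [i * index.n_targets + j for i, j in self.positives], dtype=np.int64
        ))

    def label_vector(self, index: DTPIndex, node_ids: np.ndarray) -> np.ndarray:
        pos = set(self.positive_node_ids(index).tolist())
        return np.asarray([1 if int(u) in pos else 0 for u in node_ids], dtype=np.int64)


@dataclass
class DTPFeatures:
    """Lazy pair features: concat(drug embedding, target embedding)."""

    drug_embeddings: EmbeddingMatrix
    target_embeddings: EmbeddingMatrix
    index: DTPIndex = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index is None:
            self.index = DTPIndex(self.drug_embeddings.entity_ids, self.target_embeddings.entity_ids)
        if len(self.drug_embeddings.entity_ids) != self.index.n_drugs:
            raise ValueError("drug embedding rows do not match index")
        if len(self.target_embeddings.entity_ids) != self.index.n_targets:
            raise ValueError("target embedding rows do not match index")

    @property
    def dim(self) -> int:
        return self.drug_embeddings.dim + self.target_embeddings.dim

    def pair_feature(self, i: int, j: int) -> np.ndarray:
        """Feature of pair (i, j): drug vector followed by target vector."""
        self.index.pair_id(i, j)  # bounds check
        return np.concatenate(
            [self.drug_embeddings.vectors[i], self.target_embeddings.vectors[j]]
        )

    def matrix_for(self, node_ids: np.ndarray) -> np.ndarray:
        """Feature rows for many pair nodes at once."""
        node_ids = np.asarray(node_ids, dtype=np.int64)
        if node_ids.size and (node_ids.min() < 0 or node_ids.max() >= self.index.n_pairs):
            raise IndexError("pair node id out of range")
        i, j = np.divmod(node_ids, self.index.n_targets)
        return np.concatenate(
            [self.drug_embeddings.vectors[i], self.target_embeddings.vectors[j]], axis=1
        )


@dataclass
class BalancedSample:
    """All positive pair nodes plus an equal number of sampled negatives."""

    node_ids: np.ndarray
    labels: np.ndarray
    seed: int


def sample_balanced(labels: DTPLabels, index: DTPIndex, seed: int = 0) -> BalancedSample:
    """All positives plus a uniform without-replacement sample of
    zero-labeled pair nodes of equal count.

    The negative universe is every pair not known to interact; the two
    sets are disjoint by construction.  Deterministic for a fixed seed.
    """
    pos = labels.positive_node_ids(index)
    n_pos = pos.size
    if n_pos == 0:
        raise ValueError("no positive interactions to sample around")
    n_neg_avail = index.n_pairs - n_pos
    if n_neg_avail < n_pos:
        raise ValueError(f"only {n_neg_avail} negatives available for {n_pos} positives")
    rng = np.random.default_rng(seed)
    pos_set = set(pos.tolist())
    chosen: list[int] = []
    seen: set[int] = set()
    # rejection sampling; the negative pool dwarfs the positives in practice
    while len(chosen) < n_pos:
        draw = rng.integers(0, index.n_pairs, size=2 * (n_pos - len(chosen)) + 8)
        for u in draw.tolist():
            if u in pos_set or u in seen:
                continue
            seen.add(u)
            chosen.append(u)
            if len(chosen) == n_pos:
                break
    neg = np.asarray(chosen, dtype=np.int64)
    node_ids = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(n_pos, dtype=np.int64), np.zeros(n_pos, dtype=np.int64)])
    return BalancedSample(node_ids=node_ids, labels=y, seed=seed)
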