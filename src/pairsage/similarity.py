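"""Entity-entity similarity networks and their fusion.

Drug-target interaction prediction by similarity assumes that similar drugs
bind similar targets.  This module turns heterogeneous association evidence
(drug-drug interactions, drug-disease and drug-side-effect links, chemical
fingerprints, protein-protein interactions, protein-disease links, amino-acid
sequences) into homogeneous per-entity-type graphs:

1. each association source yields a square similarity matrix ``S`` — Jaccard
   for binary association profiles, Tanimoto for fingerprints, normalized
   Smith-Waterman for sequences;
2. each ``S`` is binarized with a threshold ``alpha`` (edge iff ``S_ij > alpha``);
3. the binary networks of one entity type are fused by element-wise OR
   ("see one, get one") into a single homogeneous adjacency matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: the 20 standard amino acids
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AssociationMatrix:
    """Binary entity x attribute incidence matrix (e.g. drug x disease)."""

    entity_ids: list[str]
    attribute_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if self.values.shape != (len(self.entity_ids), len(self.attribute_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match id lists "
                f"({len(self.entity_ids)} x {len(self.attribute_ids)})"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association values must be binary")
        self.values = self.values.astype(np.uint8)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1]."""

    entity_ids: list[str]
    values: np.ndarray
    kind: str = "jaccard"


@dataclass
class BinaryNetwork:
    """Thresholded similarity: simple-graph adjacency (zero diagonal)."""

    entity_ids: list[str]
    values: np.ndarray
    alpha: float
    name: str = ""


@dataclass
class HomogeneousNetwork:
    """OR-fusion of several binary networks over the same entities."""

    entity_ids: list[str]
    values: np.ndarray
    sources: list[str] = field(default_factory=list)

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def density(self) -> float:
        n = self.n_entities
        if n < 2:
            return 0.0
        return float(self.values.sum()) / (n * (n - 1))


def _binary_profile_similarity(values: np.ndarray) -> np.ndarray:
    """|A∩B| / |A∪B| for every pair of binary rows; 0/0 defined as 0."""
    v = values.astype(np.float64)
    inter = v @ v.T
    sizes = v.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return sim


def jaccard_similarity(assoc: AssociationMatrix) -> SimilarityMatrix:
    """Jaccard coefficient between the association profiles of every
    entity pair.

    Two entities with identical non-empty profiles score 1; disjoint
    profiles score 0.  A pair involving an all-zero profile is defined
    as 0 (no shared evidence implies no similarity), including on the
    diagonal.
    """
    if len(assoc.entity_ids) == 0:
        raise ValueError("empty association matrix")
    sim = _binary_profile_similarity(assoc.values)
    n_empty = int((assoc.values.sum(axis=1) == 0).sum())
    if n_empty:
        logger.info("jaccard: %d all-zero profiles, similarity defined as 0", n_empty)
    return SimilarityMatrix(list(assoc.entity_ids), sim, kind="jaccard")


def tanimoto_similarity(fingerprints: AssociationMatrix) -> SimilarityMatrix:
    """Tanimoto coefficient c / (a + b - c) between binary fingerprints.

    ``a`` and ``b`` are the set-bit counts of the two fingerprints and
    ``c`` the count of shared bits.  A pair of all-zero fingerprints is
    defined as 0 and flagged in the log.
    """
    if len(fingerprints.entity_ids) == 0:
        raise ValueError("empty fingerprint matrix")
    sim = _binary_profile_similarity(fingerprints.values)
    n_empty = int((fingerprints.values.sum(axis=1) == 0).sum())
    if n_empty:
        logger.warning("tanimoto: %d all-zero fingerprints, similarity set to 0", n_empty)
    return SimilarityMatrix(list(fingerprints.entity_ids), sim, kind="tanimoto")


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman_similarity(
    sequences: list[tuple[str, str]],
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    normalize: bool = True,
    x_tolerant: bool = True,
) -> SimilarityMatrix:
    """Pairwise local-alignment (Smith-Waterman) similarity of protein
    sequences.

    Raw optimal local-alignment scores ``SW(i, j)`` are computed with an
    affine gap penalty (opening a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``).  With ``normalize=True`` the
    stored value is ``SW(i, j) / sqrt(SW(i, i) * SW(j, j))`` so that the
    diagonal is 1 and values live on the same [0, 1] scale as the
    Jaccard/Tanimoto matrices; ``normalize=False`` keeps raw scores.

    Parameters
    ----------
    sequences
        ``(id, amino-acid string)`` pairs.
    matrix
        Substitution matrix name (any matrix biopython ships, e.g.
        ``"BLOSUM62"``).
    x_tolerant
        Accept the ambiguity code ``X`` in addition to the 20 standard
        residues.
    """
    if not sequences:
        raise ValueError("no sequences given")
    allowed = AMINO_ACIDS | ({"X"} if x_tolerant else set())
    for sid, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence for {sid!r}")
        bad = set(seq.upper()) - allowed
        if bad:
            raise ValueError(f"unknown residue(s) {sorted(bad)} in sequence {sid!r}")

    aligner = _make_aligner(matrix, gap_open, gap_extend)
    n = len(sequences)
    raw = np.zeros((n, n))
    seqs = [s.upper() for _, s in sequences]
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = aligner.score(seqs[i], seqs[j])
    if not normalize:
        return SimilarityMatrix([sid for sid, _ in sequences], raw, kind="smith_waterman")
    self_scores = np.diag(raw).copy()
    if (self_scores <= 0).any():
        raise ValueError("non-positive self-alignment score; cannot normalize")
    norm = raw / np.sqrt(self_scores[:, None] * self_scores[None, :])
    return SimilarityMatrix([sid for sid, _ in sequences], np.clip(norm, 0.0, 1.0), kind="smith_waterman")


def binarize(sim: SimilarityMatrix, alpha: float, name: str = "") -> BinaryNetwork:
    """Edge iff ``S_ij > alpha`` (strict); the diagonal is forced to 0 so
    the result is a simple-graph adjacency matrix."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    values = (sim.values > alpha).astype(np.uint8)
    np.fill_diagonal(values, 0)
    net = BinaryNetwork(list(sim.entity_ids), values, alpha, name=name or sim.kind)
    n = len(net.entity_ids)
    if n > 1:
        logger.info(
            "binarize(%s, alpha=%.3g): edge density %.4f",
            net.name, alpha, values.sum() / (n * (n - 1)),
        )
    return net


def fuse_networks(nets: list[BinaryNetwork]) -> HomogeneousNetwork:
    """Element-wise OR of binary networks: an edge in any source network
    is an edge of the homogeneous network ("see one, get one")."""
    if not nets:
        raise ValueError("no networks to fuse")
    ids = nets[0].entity_ids
    for net in nets[1:]:
        if net.entity_ids != ids:
            raise ValueError("entity id lists differ between networks being fused")
    fused = np.zeros_like(nets[0].values, dtype=np.uint8)
    for net in nets:
        fused |= net.values.astype(np.uint8)
    np.fill_diagonal(fused, 0)
    return HomogeneousNetwork(list(ids), fused, sources=[n.name for n in nets])
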