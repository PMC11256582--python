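"""Synthetic heterogeneous drug/target data with a planted interaction
signal.

The generator emulates the statistical structure the similarity-based
prediction pipeline assumes — "similar drugs interact with similar
targets" — without any real chemistry or biology:

* drugs and targets are partitioned into clusters;
* every association source (drug-drug interaction, drug-disease,
  drug-side-effect, protein-protein interaction, protein-disease) gives
  each entity the attribute block of its cluster, with independent
  bit-flip noise;
* fingerprints share a bit block per drug cluster, again noise-flipped;
* protein sequences are random backbones with a cluster-specific motif
  implanted, so local alignment recovers the cluster structure;
* interactions are planted between matched (drug-cluster, target-cluster)
  pairs at a configured density, plus a uniform background rate.

Everything derives from one root seed, split per artifact, so each file
is independently reproducible and a fixed seed yields byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .similarity import AssociationMatrix

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: association sources on the drug side / target side
DRUG_SOURCES = ("drug_drug", "drug_disease", "drug_side_effect")
TARGET_SOURCES = ("ppi", "protein_disease")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    The defaults define the standard desk-scale dataset: 60 drugs and 90
    targets in 4 + 4 matched clusters, 5% bit-flip noise on every
    association source, and interactions planted within matched cluster
    pairs at density 0.8 over a 0.002 background (the planted
    similar-binds-similar rule is the majority behavior within a matched
    block, so it is identifiable from cluster-level features).
    """

    n_drugs: int = 60
    n_targets: int = 90
    n_diseases: int = 40
    n_side_effects: int = 30
    n_drug_clusters: int = 4
    n_target_clusters: int = 4
    fingerprint_bits: int = 128
    seq_length: int = 160
    assoc_noise: float = 0.05
    interaction_density: float = 0.8
    background_density: float = 0.002
    seed: int = 0
    #: per-source noise overrides, e.g. {"ppi": 0.5}; "fingerprints" and
    #: "sequence" are also recognized
    noise_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_drug_clusters > self.n_drugs or self.n_target_clusters > self.n_targets:
            raise ValueError("more clusters than entities")
        for p in (self.assoc_noise, self.interaction_density, self.background_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def noise_for(self, source: str) -> float:
        return float(self.noise_overrides.get(source, self.assoc_noise))

    @classmethod
    def sequence_dominant(cls, seed: int = 0, **kw) -> "SynthConfig":
        """Conditions in which the protein-sequence network carries most
        of the target-side signal: the other target-side sources are
        noised to uninformativeness."""
        overrides = {"ppi": 0.5, "protein_disease": 0.5, "sequence": 0.0}
        overrides.update(kw.pop("noise_overrides", {}))
        return cls(seed=seed, noise_overrides=overrides, **kw)


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything the pipeline consumes."""

    config: SynthConfig
    drug_ids: list[str]
    target_ids: list[str]
    associations: dict[str, AssociationMatrix]
    fingerprints: AssociationMatrix
    sequences: list[tuple[str, str]]
    interactions: list[tuple[str, str]]
    drug_clusters: np.ndarray
    target_clusters: np.ndarray

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the dataset in exactly the formats the pipeline reads."""
        from . import io as pio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, assoc in self.associations.items():
            p = outdir / f"{name}.tsv"
            pio.write_edge_list(p, _matrix_edges(assoc))
            paths[name] = p
        paths["fingerprints"] = outdir / "fingerprints.tsv"
        pio.write_fingerprints(paths["fingerprints"], self.fingerprints)
        paths["sequences"] = outdir / "sequences.fasta"
        pio.write_fasta(paths["sequences"], self.sequences)
        paths["interactions"] = outdir / "interactions.tsv"
        pio.write_edge_list(paths["interactions"], self.interactions)
        paths["ground_truth"] = outdir / "ground_truth.json"
        pio.write_json(
            paths["ground_truth"],
            {
                "drug_clusters": {d: int(c) for d, c in zip(self.drug_ids, self.drug_clusters)},
                "target_clusters": {t: int(c) for t, c in zip(self.target_ids, self.target_clusters)},
                "seed": self.config.seed,
            },
        )
        return paths


def _matrix_edges(assoc: AssociationMatrix) -> list[tuple[str, str]]:
    rows, cols = np.nonzero(assoc.values)
    return [(assoc.entity_ids[r], assoc.attribute_ids[c]) for r, c in zip(rows, cols)]


def _cluster_assignment(n: int, k: int) -> np.ndarray:
    """Contiguous near-equal blocks: entity e belongs to cluster e*k//n."""
    return (np.arange(n) * k) // n


def _block_profiles(
    clusters: np.ndarray,
    n_attrs: int,
    n_clusters: int,
    noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cluster-block attribute profiles with independent bit-flip noise."""
    attr_cluster = _cluster_assignment(n_attrs, n_clusters)
    base = (attr_cluster[None, :] == clusters[:, None]).astype(np.uint8)
    flips = rng.random(base.shape) < noise
    return base ^ flips.astype(np.uint8)


def generate(config: SynthConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic input bundle for one seed."""
    cfg = config or SynthConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(9)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["drug_drug", "drug_disease", "drug_side_effect", "ppi",
             "protein_disease", "fingerprints", "sequence", "interactions", "misc"],
            streams,
        )
    }

    drug_ids = [f"D{i:03d}" for i in range(cfg.n_drugs)]
    target_ids = [f"T{j:03d}" for j in range(cfg.n_targets)]
    disease_ids = [f"dis{k:03d}" for k in range(cfg.n_diseases)]
    se_ids = [f"se{k:03d}" for k in range(cfg.n_side_effects)]
    bit_ids = [f"b{k:03d}" for k in range(cfg.fingerprint_bits)]

    dclust = _cluster_assignment(cfg.n_drugs, cfg.n_drug_clusters)
    tclust = _cluster_assignment(cfg.n_targets, cfg.n_target_clusters)

    associations = {
        "drug_drug": AssociationMatrix(
            drug_ids, drug_ids,
            _block_profiles(dclust, cfg.n_drugs, cfg.n_drug_clusters,
                            cfg.noise_for("drug_drug"), rngs["drug_drug"]),
        ),
        "drug_disease": AssociationMatrix(
            drug_ids, disease_ids,
            _block_profiles(dclust, cfg.n_diseases, cfg.n_drug_clusters,
                            cfg.noise_for("drug_disease"), rngs["drug_disease"]),
        ),
        "drug_side_effect": AssociationMatrix(
            drug_ids, se_ids,
            _block_profiles(dclust, cfg.n_side_effects, cfg.n_drug_clusters,
                            cfg.noise_for("drug_side_effect"), rngs["drug_side_effect"]),
        ),
        "ppi": AssociationMatrix(
            target_ids, target_ids,
            _block_profiles(tclust, cfg.n_targets, cfg.n_target_clusters,
                            cfg.noise_for("ppi"), rngs["ppi"]),
        ),
        "protein_disease": AssociationMatrix(
            target_ids, disease_ids,
            _block_profiles(tclust, cfg.n_diseases, cfg.n_target_clusters,
                            cfg.noise_for("protein_disease"), rngs["protein_disease"]),
        ),
    }

    fingerprints = AssociationMatrix(
        drug_ids, bit_ids,
        _block_profiles(dclust, cfg.fingerprint_bits, cfg.n_drug_clusters,
                        cfg.noise_for("fingerprints"), rngs["fingerprints"]),
    )

    # sequences: random backbone + implanted cluster motif (length L/4)
    seq_rng = rngs["sequence"]
    motif_len = max(4, cfg.seq_length // 4)
    motifs = [
        "".join(seq_rng.choice(AA, size=motif_len))
        for _ in range(cfg.n_target_clusters)
    ]
    seq_noise = cfg.noise_for("sequence")
    sequences = []
    for t, c in zip(target_ids, tclust):
        backbone = seq_rng.choice(AA, size=cfg.seq_length)
        pos = int(seq_rng.integers(0, cfg.seq_length - motif_len + 1))
        motif = np.array(list(motifs[c]))
        if seq_noise > 0:
            mutate = seq_rng.random(motif_len) < seq_noise
            motif = np.where(mutate, seq_rng.choice(AA, size=motif_len), motif)
        backbone[pos : pos + motif_len] = motif
        sequences.append((t, "".join(backbone)))

    # planted interactions: drug cluster k binds target cluster k (mod)
    int_rng = rngs["interactions"]
    matched = dclust[:, None] == (tclust[None, :] % cfg.n_drug_clusters)
    p = np.where(matched, cfg.interaction_density, cfg.background_density)
    hits = int_rng.random((cfg.n_drugs, cfg.n_targets)) < p
    if not hits.any():  # degenerate config: force one planted interaction
        hits[0, 0] = True
    interactions = [
        (drug_ids[i], target_ids[j]) for i, j in zip(*np.nonzero(hits))
    ]

    return SyntheticDataset(
        config=cfg,
        drug_ids=drug_ids,
        target_ids=target_ids,
        associations=associations,
        fingerprints=fingerprints,
        sequences=sequences,
        interactions=interactions,
        drug_clusters=dclust,
        target_clusters=tclust,
    )
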