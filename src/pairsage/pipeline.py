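"""End-to-end orchestration: similarity fusion -> DeepWalk -> pair graph
-> GraphSAGE -> classifier -> evaluation and ranked predictions.

A run is driven by a single :class:`PipelineConfig` (loadable from YAML).
In file-based runs each similarity matrix is cached under
``<outdir>/cache`` keyed by a hash of the inputs, so re-running with a
different binarization threshold alpha recomputes exactly the
similarity-downstream stages and nothing upstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .classify import (
    EvalReport,
    cross_validate,
    rank_predictions,
    repeated_split_eval,
    train_classifier,
)
from .dtp import BalancedSample, DTPFeatures, DTPIndex, DTPLabels, sample_balanced
from .embedding import DeepWalkParams, EmbeddingMatrix, embed_network
from .sage import FullDTPSampler, SageConfig, dense_feature_fn, train as sage_train
from .similarity import (
    AssociationMatrix,
    SimilarityMatrix,
    binarize,
    fuse_networks,
    jaccard_similarity,
    smith_waterman_similarity,
    tanimoto_similarity,
)
from .synth import SyntheticDataset

logger = logging.getLogger(__name__)

#: network name -> similarity kind, per side
DRUG_NETWORKS = {
    "drug_drug": "jaccard",
    "drug_side_effect": "jaccard",
    "drug_disease": "jaccard",
    "drug_structure": "tanimoto",
}
TARGET_NETWORKS = {
    "ppi": "jaccard",
    "protein_disease": "jaccard",
    "protein_sequence": "smith_waterman",
}
ALL_NETWORKS = {**DRUG_NETWORKS, **TARGET_NETWORKS}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its context."""


@dataclass
class PipelineConfig:
    """Everything one run needs; hyperparameters keep their conventional
    names (alpha, fanouts S1/S2, learning_rate)."""

    inputs: dict[str, str] = field(default_factory=dict)
    networks: dict[str, bool] = field(default_factory=dict)
    alpha: float | dict = 0.5
    deepwalk: DeepWalkParams = field(default_factory=DeepWalkParams)
    sage: SageConfig = field(default_factory=SageConfig)
    classifier: str = "rf"
    protocol: str = "cv"  # cv | repeated_split
    n_folds: int = 5
    n_repeats: int = 50
    train_frac: float = 0.75
    retrain_per_fold: bool = True
    subgraph_only: bool = False
    do_ranking: bool = True
    top_k: int = 100
    seed: int = 0
    outdir: str = "pairsage_out"

    def __post_init__(self) -> None:
        for name in self.networks:
            if name not in ALL_NETWORKS:
                raise ValueError(f"unknown network flag {name!r}")
        full = {n: True for n in ALL_NETWORKS}
        full.update(self.networks)
        self.networks = full
        if not any(self.networks[n] for n in DRUG_NETWORKS):
            raise ValueError("at least one drug network must be enabled")
        if not any(self.networks[n] for n in TARGET_NETWORKS):
            raise ValueError("at least one target network must be enabled")

    def alpha_for(self, network: str) -> float:
        if isinstance(self.alpha, dict):
            return float(self.alpha.get(network, self.alpha.get("default", 0.5)))
        return float(self.alpha)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "deepwalk" in raw:
            raw["deepwalk"] = DeepWalkParams(**raw["deepwalk"])
        sg = raw.pop("graphsage", raw.pop("sage", None))
        if sg is not None:
            if "fanouts" in sg:
                sg["fanouts"] = tuple(sg["fanouts"])
            raw["sage"] = SageConfig(**sg)
        cfg = cls(**raw)
        for key, p in cfg.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input {key!r}: no such file {p}")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sage"]["fanouts"] = list(d["sage"]["fanouts"])
        return d

    def config_hash(self) -> str:
        return _hash(self.to_dict())


def _hash(obj) -> str:
    return hashlib.sha1(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineData:
    """In-memory inputs: association matrices, fingerprints, sequences
    and the known-interaction list, over fixed drug/target orderings."""

    drug_ids: list[str]
    target_ids: list[str]
    associations: dict[str, AssociationMatrix]
    fingerprints: AssociationMatrix | None
    sequences: list[tuple[str, str]] | None
    interactions: list[tuple[str, str]]

    @classmethod
    def from_synthetic(cls, ds: SyntheticDataset) -> "PipelineData":
        return cls(
            drug_ids=list(ds.drug_ids),
            target_ids=list(ds.target_ids),
            associations=dict(ds.associations),
            fingerprints=ds.fingerprints,
            sequences=list(ds.sequences),
            interactions=list(ds.interactions),
        )

    @classmethod
    def from_paths(cls, inputs: dict[str, str]) -> "PipelineData":
        """Load TSV/FASTA inputs.  Expected keys: ``interactions`` plus
        any of ``drug_drug``, ``drug_disease``, ``drug_side_effect``,
        ``fingerprints``, ``ppi``, ``protein_disease``, ``sequences``."""
        if "interactions" not in inputs:
            raise PipelineError("inputs must include 'interactions'")
        interactions = pio.read_edge_list(inputs["interactions"])
        raw_edges = {
            k: pio.read_edge_list(p)
            for k, p in inputs.items()
            if k in ("drug_drug", "drug_disease", "drug_side_effect", "ppi", "protein_disease")
        }
        fingerprints = (
            pio.read_fingerprints(inputs["fingerprints"]) if "fingerprints" in inputs else None
        )
        sequences = pio.read_fasta(inputs["sequences"]) if "sequences" in inputs else None

        drug_ids: set[str] = {d for d, _ in interactions}
        for k in ("drug_drug", "drug_disease", "drug_side_effect"):
            drug_ids |= {a for a, _ in raw_edges.get(k, [])}
        if fingerprints is not None:
            drug_ids |= set(fingerprints.entity_ids)
        target_ids: set[str] = {t for _, t in interactions}
        for k in ("ppi", "protein_disease"):
            target_ids |= {a for a, _ in raw_edges.get(k, [])}
        if sequences is not None:
            target_ids |= {sid for sid, _ in sequences}
        drugs, targets = sorted(drug_ids), sorted(target_ids)

        associations = {}
        for k, edges in raw_edges.items():
            ents = drugs if k.startswith("drug") else targets
            attrs = drugs if k == "drug_drug" else targets if k == "ppi" else None
            associations[k] = pio.association_from_edges(edges, ents, attrs)
        if fingerprints is not None and list(fingerprints.entity_ids) != drugs:
            order = {e: i for i, e in enumerate(fingerprints.entity_ids)}
            missing = [d for d in drugs if d not in order]
            if missing:
                raise PipelineError(f"fingerprints missing for drugs {missing[:5]}")
            fingerprints = AssociationMatrix(
                drugs, list(fingerprints.attribute_ids),
                fingerprints.values[[order[d] for d in drugs]],
            )
        if sequences is not None:
            seq_map = dict(sequences)
            missing = [t for t in targets if t not in seq_map]
            if missing:
                raise PipelineError(f"sequences missing for targets {missing[:5]}")
            sequences = [(t, seq_map[t]) for t in targets]
        return cls(drugs, targets, associations, fingerprints, sequences, interactions)


@dataclass
class PipelineResult:
    report: EvalReport
    predictions: pd.DataFrame
    h_d_density: float
    h_t_density: float
    n_positives: int
    timings: dict[str, float]
    drug_embeddings: EmbeddingMatrix | None = None
    target_embeddings: EmbeddingMatrix | None = None


# --------------------------------------------------------------------------
# stages


def compute_similarity(data: PipelineData, name: str) -> SimilarityMatrix:
    """One similarity matrix by network name."""
    try:
        if name == "drug_structure":
            if data.fingerprints is None:
                raise PipelineError("drug_structure enabled but no fingerprints given")
            return tanimoto_similarity(data.fingerprints)
        if name == "protein_sequence":
            if data.sequences is None:
                raise PipelineError("protein_sequence enabled but no sequences given")
            return smith_waterman_similarity(data.sequences)
        if name not in ALL_NETWORKS:
            raise PipelineError(f"unknown network {name!r}")
        if name not in data.associations:
            raise PipelineError(f"network {name!r} enabled but input missing")
        return jaccard_similarity(data.associations[name])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface the failing stage
        raise PipelineError(f"similarity stage failed for {name!r}: {exc}") from exc


def compute_similarities(data: PipelineData, cfg: PipelineConfig) -> dict[str, SimilarityMatrix]:
    sims = {}
    for name in ALL_NETWORKS:
        if not cfg.networks.get(name, True):
            continue
        t0 = time.perf_counter()
        sims[name] = compute_similarity(data, name)
        logger.info("similarity[%s]: %.2fs", name, time.perf_counter() - t0)
    return sims


def build_homogeneous(sims: dict, cfg: PipelineConfig):
    """Binarize each similarity with its alpha and OR-fuse per side."""
    drug_nets, target_nets = [], []
    for name, sim in sims.items():
        net = binarize(sim, cfg.alpha_for(name), name=name)
        (drug_nets if name in DRUG_NETWORKS else target_nets).append(net)
    if not drug_nets or not target_nets:
        raise PipelineError("need at least one drug and one target network after fusion")
    return fuse_networks(drug_nets), fuse_networks(target_nets)


def run_core(
    data: PipelineData,
    cfg: PipelineConfig,
    permute_labels: bool = False,
    sims: dict[str, SimilarityMatrix] | None = None,
) -> PipelineResult:
    """The full pipeline on in-memory inputs.

    ``permute_labels=True`` runs the label-permutation null: the balanced
    sample's labels are shuffled before the graph network and the
    classifier ever see them, so any residual signal reflects leakage
    rather than the planted biology.  ``sims`` can inject precomputed
    similarity matrices (the cached file-based path does this).
    """
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if sims is None:
        sims = compute_similarities(data, cfg)
    h_d, h_t = build_homogeneous(sims, cfg)
    timings["similarity"] = time.perf_counter() - t0
    logger.info("H_D density %.4f | H_T density %.4f", h_d.density(), h_t.density())

    t0 = time.perf_counter()
    dw = cfg.deepwalk
    f_d = embed_network(h_d, replace(dw, seed=dw.seed + cfg.seed))
    f_t = embed_network(h_t, replace(dw, seed=dw.seed + cfg.seed + 1))
    timings["deepwalk"] = time.perf_counter() - t0

    index = DTPIndex(data.drug_ids, data.target_ids)
    labels = DTPLabels.from_edges(index, data.interactions)
    features = DTPFeatures(f_d, f_t, index)
    sample = sample_balanced(labels, index, seed=cfg.seed)
    if permute_labels:
        rng = np.random.default_rng(cfg.seed + 977)
        sample = BalancedSample(sample.node_ids, rng.permutation(sample.labels), sample.seed)

    t0 = time.perf_counter()
    sage_cfg = replace(cfg.sage, seed=cfg.sage.seed + cfg.seed)
    if cfg.protocol == "cv":
        report = cross_validate(
            index, features, sample, sage_cfg,
            classifier=cfg.classifier, n_folds=cfg.n_folds, seed=cfg.seed,
            retrain_per_fold=cfg.retrain_per_fold, subgraph_only=cfg.subgraph_only,
        )
    elif cfg.protocol == "repeated_split":
        report = repeated_split_eval(
            index, features, sample, sage_cfg,
            classifier=cfg.classifier, n_repeats=cfg.n_repeats,
            train_frac=cfg.train_frac, seed=cfg.seed, subgraph_only=cfg.subgraph_only,
        )
    else:
        raise PipelineError(f"unknown protocol {cfg.protocol!r}")
    report.config_hash = cfg.config_hash()
    timings["evaluation"] = time.perf_counter() - t0

    # final model on the full balanced sample -> ranked candidate list
    t0 = time.perf_counter()
    if cfg.do_ranking:
        sampler = FullDTPSampler(index)
        feature_fn = dense_feature_fn(
            features.matrix_for, index.n_pairs, np.dtype(sage_cfg.dtype)
        )
        model, _ = sage_train(
            index, feature_fn, sample.node_ids, sample.labels, sage_cfg, sampler
        )
        if index.n_pairs <= 200_000:
            candidates = np.arange(index.n_pairs, dtype=np.int64)
        else:  # desk-scale guard: rank only the sampled nodes on huge grids
            candidates = sample.node_ids
        refined = model.refine(candidates, feature_fn, sampler, seed=cfg.seed)
        clf = train_classifier(
            model.refine(sample.node_ids, feature_fn, sampler, seed=cfg.seed).vectors,
            sample.labels, kind=cfg.classifier, seed=cfg.seed,
        )
        scores = clf.predict_proba(refined.vectors)[:, 1]
        predictions = rank_predictions(
            scores, candidates, index, known=labels.positives, top_k=cfg.top_k
        )
    else:
        predictions = pd.DataFrame(
            columns=["rank", "drug_id", "target_id", "score", "known"]
        )
    timings["ranking"] = time.perf_counter() - t0
    for stage, secs in timings.items():
        logger.info("stage %-12s %.2fs", stage, secs)

    return PipelineResult(
        report=report,
        predictions=predictions,
        h_d_density=h_d.density(),
        h_t_density=h_t.density(),
        n_positives=labels.n_positives(),
        timings=timings,
        drug_embeddings=f_d,
        target_embeddings=f_t,
    )


# --------------------------------------------------------------------------
# cached file-based runs


def _sim_cache_path(cache_dir: Path, name: str, key: str) -> Path:
    return cache_dir / f"similarity-{name}-{key}.npz"


def run(config: PipelineConfig, data: PipelineData | None = None) -> PipelineResult:
    """File-based pipeline run; similarity matrices (the expensive,
    alpha-independent stage) are cached under ``<outdir>/cache``.
    ``data`` can be passed to skip input loading (e.g. a freshly
    generated synthetic bundle)."""
    outdir = Path(config.outdir)
    cache_dir = outdir / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = PipelineData.from_paths(config.inputs)

    input_key = _hash(
        {
            "drugs": data.drug_ids,
            "targets": data.target_ids,
            "interactions": sorted(data.interactions),
        }
    )
    sims: dict[str, SimilarityMatrix] = {}
    for name in ALL_NETWORKS:
        if not config.networks.get(name, True):
            continue
        path = _sim_cache_path(cache_dir, name, input_key)
        if path.exists():
            logger.info("similarity[%s]: cache hit", name)
            with np.load(path, allow_pickle=False) as z:
                sims[name] = SimilarityMatrix(
                    [str(x) for x in z["ids"]], z["values"], str(z["kind"])
                )
        else:
            sims[name] = compute_similarity(data, name)
            np.savez(
                path,
                values=sims[name].values,
                ids=np.asarray(sims[name].entity_ids),
                kind=sims[name].kind,
            )

    result = run_core(data, config, sims=sims)

    pio.write_json(
        outdir / "report.json",
        {
            "mean": result.report.mean,
            "folds": result.report.folds,
            "config_hash": result.report.config_hash,
            "extras": result.report.extras,
            "h_d_density": result.h_d_density,
            "h_t_density": result.h_t_density,
            "n_positives": result.n_positives,
        },
    )
    result.report.to_frame().to_csv(outdir / "report.csv", index=False)
    result.predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    if result.drug_embeddings is not None:
        pio.write_embeddings(outdir / "drug_embeddings.tsv", result.drug_embeddings)
        pio.write_embeddings(outdir / "target_embeddings.tsv", result.target_embeddings)
    return result


# --------------------------------------------------------------------------
# sensitivity sweeps


def sweep(
    data: PipelineData,
    base: PipelineConfig,
    grid: dict[str, list],
) -> pd.DataFrame:
    """Grid sweep over ``learning_rate``, ``aggregator`` and/or
    ``classifier``; one tidy row per grid point per fold.  Duplicate grid
    points (identical effective config) are skipped via config hash."""
    allowed = {"learning_rate", "aggregator", "classifier"}
    bad = set(grid) - allowed
    if bad:
        raise ValueError(f"sweep supports {sorted(allowed)}, got extra {sorted(bad)}")
    keys = sorted(grid)
    # similarity matrices do not depend on the sweep axes: compute once
    sims = compute_similarities(data, base)
    rows = []
    seen: set[str] = set()
    for values in product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        sage_kw = {k: v for k, v in point.items() if k in ("learning_rate", "aggregator")}
        cfg = replace(
            base,
            sage=replace(base.sage, **sage_kw),
            classifier=point.get("classifier", base.classifier),
        )
        h = cfg.config_hash()
        if h in seen:
            continue
        seen.add(h)
        result = run_core(data, cfg, sims=sims)
        for fold_idx, fold in enumerate(result.report.folds):
            rows.append({**point, "fold": fold_idx, **fold})
    return pd.DataFrame(rows)
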