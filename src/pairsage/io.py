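"""Readers and writers for the plain-text formats the pipeline consumes.

Association networks travel as two-column TSV edge lists, fingerprints as
``id<TAB>bitstring`` lines, protein sequences as FASTA, matrices and
embeddings as TSV with id headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .embedding import EmbeddingMatrix
from .similarity import AssociationMatrix, SimilarityMatrix


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(path: str | Path, edges: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def association_from_edges(
    edges: list[tuple[str, str]],
    entity_ids: list[str] | None = None,
    attribute_ids: list[str] | None = None,
) -> AssociationMatrix:
    """Build a binary incidence matrix from an edge list.

    Id orderings default to sorted first-column / second-column values;
    passing explicit lists pins the row/column order (required when
    several networks must share one entity ordering).
    """
    if entity_ids is None:
        entity_ids = sorted({a for a, _ in edges})
    if attribute_ids is None:
        attribute_ids = sorted({b for _, b in edges})
    erow = {e: i for i, e in enumerate(entity_ids)}
    acol = {a: j for j, a in enumerate(attribute_ids)}
    values = np.zeros((len(entity_ids), len(attribute_ids)), dtype=np.uint8)
    for a, b in edges:
        if a not in erow:
            raise KeyError(f"edge references unknown entity {a!r}")
        if b not in acol:
            raise KeyError(f"edge references unknown attribute {b!r}")
        values[erow[a], acol[b]] = 1
    return AssociationMatrix(list(entity_ids), list(attribute_ids), values)


def read_fingerprints(path: str | Path) -> AssociationMatrix:
    ids, rows = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fid, bits = line.split("\t")
            if set(bits) - {"0", "1"}:
                raise ValueError(f"{path}:{line_no}: fingerprint is not a 0/1 string")
            ids.append(fid)
            rows.append([int(b) for b in bits])
    if not ids:
        raise ValueError(f"{path}: no fingerprints")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: fingerprints differ in length")
    bit_ids = [f"b{k:03d}" for k in range(width)]
    return AssociationMatrix(ids, bit_ids, np.asarray(rows, dtype=np.uint8))


def write_fingerprints(path: str | Path, fp: AssociationMatrix) -> None:
    with open(path, "w") as fh:
        for eid, row in zip(fp.entity_ids, fp.values):
            fh.write(f"{eid}\t{''.join(str(int(b)) for b in row)}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, sequences: list[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


def write_matrix(path: str | Path, ids: list[str], values: np.ndarray) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.index], df.to_numpy()


def write_similarity(path: str | Path, sim: SimilarityMatrix) -> None:
    write_matrix(path, sim.entity_ids, sim.values)


def write_embeddings(path: str | Path, emb: EmbeddingMatrix) -> None:
    df = pd.DataFrame(emb.vectors, index=emb.entity_ids)
    df.to_csv(path, sep="\t", header=False)


def read_embeddings(path: str | Path) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, header=None)
    return EmbeddingMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
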