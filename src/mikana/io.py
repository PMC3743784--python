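"""Tab-separated readers/writers for expression matrices, sample metadata,
and edge lists (plus SIF export), with light provenance headers.

All files are UTF-8 TSV; lines starting ``#`` are provenance/comment lines.
Expression matrices have genes as rows (first column the gene id) and
samples as columns, with a metadata sidecar covering every sample column.
Edge lists carry ``parent  child  sign`` (and ``weight`` for inferred
networks); identifiers are opaque strings such as probe ids.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, META_COLUMNS
from .network import GeneNetwork

__all__ = [
    "read_expression", "write_expression",
    "read_edges", "write_edges",
    "read_sif", "write_sif",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a configuration object's repr (provenance tag)."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k}={v}" for k, v in provenance.items()]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression(
    data: ExpressionDataset,
    matrix_path,
    meta_path,
    provenance: dict | None = None,
) -> None:
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    header = _provenance_lines(provenance)
    with open(matrix_path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        data.to_frame().rename_axis("gene").reset_index().to_csv(
            fh, sep="\t", index=False, lineterminator="\n")
    with open(meta_path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        data.meta[META_COLUMNS].to_csv(fh, sep="\t", index=False,
                                       lineterminator="\n")


def read_expression(matrix_path, meta_path) -> ExpressionDataset:
    """Load and validate a matrix + metadata pair.

    Raises ``ValueError`` naming the offending samples when metadata does not
    cover every sample column; duplicate gene/probe ids are permitted but
    flagged with a warning.
    """
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    mat = pd.read_csv(matrix_path, sep="\t", comment="#")
    if mat.columns[0] != "gene":
        raise ValueError(
            f"{matrix_path}: first column must be 'gene', got {mat.columns[0]!r}"
        )
    genes = mat["gene"].astype(str).tolist()
    dupes = mat["gene"][mat["gene"].duplicated()]
    if len(dupes):
        warnings.warn(
            f"{matrix_path}: duplicated gene/probe ids: "
            f"{sorted(set(dupes.astype(str)))[:5]}"
        )
    values = mat.drop(columns="gene")
    try:
        arr = values.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{matrix_path}: non-numeric expression cell: {exc}")
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"{meta_path}: missing columns {missing_cols}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    sample_ids = [str(c) for c in values.columns]
    covered = set(meta["sample_id"])
    uncovered = [s for s in sample_ids if s not in covered]
    if uncovered:
        raise ValueError(
            f"{meta_path}: metadata missing for sample(s) {uncovered[:5]}"
        )
    meta = meta.set_index("sample_id", drop=False).loc[sample_ids]
    return ExpressionDataset(values=arr, genes=genes,
                             meta=meta.reset_index(drop=True))


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def write_edges(net: GeneNetwork, path, provenance: dict | None = None) -> None:
    """Tab-separated ``parent  child  sign  [weight]`` with a gene-universe
    header so the network round-trips losslessly."""
    path = Path(path)
    names = net.gene_names
    with_weights = net.weights is not None
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write(f"# n_genes={net.n_genes}\n")
        fh.write("# genes=" + "\t".join(names) + "\n")
        cols = ["parent", "child", "sign"] + (["weight"] if with_weights else [])
        fh.write("\t".join(cols) + "\n")
        for (a, b) in sorted(net.edges):
            row = [names[a], names[b], str(net.edges[(a, b)])]
            if with_weights:
                row.append(repr(net.weights.get((a, b), float("nan"))))
            fh.write("\t".join(row) + "\n")


def read_edges(path) -> GeneNetwork:
    """Inverse of :func:`write_edges`.

    Self-loop rows are dropped with a warning; duplicated edges are
    deduplicated (first occurrence kept) with a warning; malformed rows
    raise with their line number.
    """
    path = Path(path)
    n_genes = None
    names: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n_genes="):
                    n_genes = int(body.split("=", 1)[1])
                elif body.startswith("genes="):
                    names = body.split("=", 1)[1].split("\t")
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                if header[:3] != ["parent", "child", "sign"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header "
                        f"'parent\\tchild\\tsign...', got {line!r}"
                    )
                continue
            rows.append((lineno, parts))
    if names is None:
        seen: dict[str, None] = {}
        for _, parts in rows:
            for g in parts[:2]:
                seen.setdefault(g, None)
        names = list(seen)
    if n_genes is None:
        n_genes = len(names)
    index = {g: i for i, g in enumerate(names)}
    has_weight = header is not None and len(header) > 3
    edges: dict[tuple[int, int], int] = {}
    weights: dict[tuple[int, int], float] = {}
    for lineno, parts in rows:
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed row {parts!r}")
        try:
            a, b = index[parts[0]], index[parts[1]]
            s = int(parts[2])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}")
        if a == b:
            warnings.warn(f"{path}:{lineno}: self-loop {parts[0]} dropped")
            continue
        if (a, b) in edges:
            warnings.warn(f"{path}:{lineno}: duplicate edge "
                          f"{parts[0]}->{parts[1]} dropped")
            continue
        edges[(a, b)] = s
        if has_weight and len(parts) > 3:
            weights[(a, b)] = float(parts[3])
    return GeneNetwork(
        n_genes=n_genes, edges=edges,
        weights=weights if has_weight else None, names=tuple(names),
    )


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def write_sif(net: GeneNetwork, path) -> None:
    """Simple-interaction-format export: ``parent activates|inhibits child``."""
    names = net.gene_names
    with open(Path(path), "w") as fh:
        for (a, b) in sorted(net.edges):
            rel = "activates" if net.edges[(a, b)] >= 0 else "inhibits"
            fh.write(f"{names[a]}\t{rel}\t{names[b]}\n")


def read_sif(path) -> GeneNetwork:
    path = Path(path)
    triples = []
    seen: dict[str, None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[1] not in ("activates", "inhibits"):
                raise ValueError(f"{path}:{lineno}: malformed SIF row {line!r}")
            triples.append(parts)
            seen.setdefault(parts[0], None)
            seen.setdefault(parts[2], None)
    names = list(seen)
    index = {g: i for i, g in enumerate(names)}
    edges = {
        (index[a], index[c]): (1 if rel == "activates" else -1)
        for a, rel, c in triples
    }
    return GeneNetwork(n_genes=len(names), edges=edges, names=tuple(names))
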