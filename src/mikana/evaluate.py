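"""Scoring of inferred networks against ground truth and against each other.

Edges are compared as directed (parent, child) pairs; sign and weight are
ignored by default (a ``strict_sign`` mode is available).  Rates with a zero
denominator are reported as NaN — an explicit "undefined" marker, never a
silent zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .network import GeneNetwork

__all__ = [
    "EdgeScore",
    "score_edges",
    "reverse_network",
    "directionality_proportions",
    "edge_overlap",
    "union_network",
    "hub_ranking",
]


@dataclass(frozen=True)
class EdgeScore:
    """Directed-edge confusion counts with derived rates.

    sensitivity = TP / (TP + FN); fdr = FP / (TP + FP).  Both are NaN when
    their denominator is zero.
    """

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def fdr(self) -> float:
        denom = self.tp + self.fp
        return self.fp / denom if denom else math.nan


def _check_universe(a: GeneNetwork, b: GeneNetwork) -> None:
    if a.n_genes != b.n_genes:
        raise ValueError(
            f"gene universes differ: {a.n_genes} vs {b.n_genes} genes"
        )
    if a.names is not None and b.names is not None and a.names != b.names:
        raise ValueError("gene name vectors differ between networks")


def score_edges(
    inferred: GeneNetwork, truth: GeneNetwork, strict_sign: bool = False
) -> EdgeScore:
    """Edge-by-edge sensitivity and FDR of ``inferred`` against ``truth``."""
    _check_universe(inferred, truth)
    if strict_sign:
        inf = set(inferred.edges.items())
        tru = set(truth.edges.items())
    else:
        inf = inferred.edge_set()
        tru = truth.edge_set()
    tp = len(inf & tru)
    return EdgeScore(tp=tp, fp=len(inf) - tp, fn=len(tru) - tp)


def reverse_network(net: GeneNetwork) -> GeneNetwork:
    """Flip the direction of every edge (signs and weights preserved)."""
    return net.reversed()


def directionality_proportions(
    inferred: GeneNetwork, truth: GeneNetwork
) -> tuple[float, float]:
    """Proportions of true edges recovered with correct vs flipped direction.

    forward  = |truth ∩ inferred| / |truth|
    reversed = |truth ∩ reverse(inferred)| / |truth|
    """
    _check_universe(inferred, truth)
    if truth.n_edges == 0:
        raise ValueError("truth network has no edges")
    tru = truth.edge_set()
    inf = inferred.edge_set()
    rev = frozenset((b, a) for a, b in inf)
    return len(tru & inf) / len(tru), len(tru & rev) / len(tru)


def edge_overlap(a: GeneNetwork, b: GeneNetwork) -> int:
    """Number of directed (parent, child) pairs shared by the two networks."""
    _check_universe(a, b)
    return len(a.edge_set() & b.edge_set())


def union_network(a: GeneNetwork, b: GeneNetwork) -> GeneNetwork:
    """Edge union of two networks (inclusion-exclusion on the edge counts).

    Where a shared edge carries conflicting signs, the sign from ``a`` is
    kept and a warning lists the conflicts.
    """
    _check_universe(a, b)
    edges = dict(b.edges)
    conflicts = []
    for pair, s in a.edges.items():
        if pair in edges and edges[pair] != s:
            conflicts.append(pair)
        edges[pair] = s
    if conflicts:
        warnings.warn(
            f"{len(conflicts)} shared edge(s) with conflicting signs "
            f"(sign of the first network kept): {conflicts[:5]}"
        )
    weights = None
    if a.weights is not None or b.weights is not None:
        weights = dict(b.weights or {})
        weights.update(a.weights or {})
        weights = {p: w for p, w in weights.items() if p in edges}
    return GeneNetwork(
        n_genes=a.n_genes, edges=edges, weights=weights,
        names=a.names or b.names,
    )


def hub_ranking(net: GeneNetwork, top_k: int | None = None) -> list[tuple[str, int]]:
    """Genes ranked by out-degree (number of target genes), descending;
    ties broken by gene label ascending.  Genes without outgoing edges are
    omitted (an empty network yields an empty ranking)."""
    names = net.gene_names
    deg = net.out_degree()
    order = sorted(
        (i for i in range(net.n_genes) if deg[i] > 0),
        key=lambda i: (-deg[i], names[i]),
    )
    if top_k is not None:
        order = order[:top_k]
    return [(names[i], int(deg[i])) for i in order]
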