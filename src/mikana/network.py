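"""Directed, signed gene-regulatory network containers and generators.

Ground-truth networks for the simulation studies are scale-free digraphs
grown by a preferential-attachment rule: every node starts with a random
uniform attachment score, and candidate edges are accepted when both
endpoints' attachment probabilities (score + current degree, normalised by
the current maximum) clear fresh uniform thresholds.  Degree therefore feeds
back into acceptance probability, producing the heavy-tailed ("rich get
richer") degree distribution, while the construction stays fully
deterministic for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GeneNetwork",
    "TopologyConfig",
    "ImpossibleTopologyError",
    "generate_scale_free",
    "assign_signs",
    "random_uniform_network",
]


class ImpossibleTopologyError(ValueError):
    """Requested edge count cannot be realised on the given node set."""


def _default_names(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n - 1)) if n else 1)
    return tuple(f"G{i:0{width}d}" for i in range(n))


@dataclass
class GeneNetwork:
    """Directed signed gene-gene interaction graph.

    Parameters
    ----------
    n_genes : int
        Number of nodes; gene indices run over ``range(n_genes)``.
    edges : mapping ``(parent, child) -> sign``
        Directed regulatory interactions; sign is +1 (activation) or -1
        (inhibition).  Self-loops and duplicate pairs are rejected.
    weights : mapping ``(parent, child) -> float``, optional
        Interaction coefficients (inferred networks only).
    names : sequence of str, optional
        Gene identifiers (opaque strings, e.g. probe ids).  Defaults to
        ``G000, G001, ...``.
    """

    n_genes: int
    edges: dict[tuple[int, int], int] = field(default_factory=dict)
    weights: dict[tuple[int, int], float] | None = None
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        self.edges = dict(self.edges)
        for (a, b), s in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop {a}->{b} not allowed")
            if not (0 <= a < self.n_genes and 0 <= b < self.n_genes):
                raise ValueError(f"edge {a}->{b} outside [0, {self.n_genes})")
            if s not in (-1, 0, 1):
                raise ValueError(f"edge {a}->{b} has invalid sign {s}")
        if self.names is not None:
            self.names = tuple(self.names)
            if len(self.names) != self.n_genes:
                raise ValueError("names length must equal n_genes")
        if self.weights is not None:
            unknown = set(self.weights) - set(self.edges)
            if unknown:
                raise ValueError(f"weights for non-edges: {sorted(unknown)[:5]}")

    # -- basic queries ---------------------------------------------------
    @property
    def gene_names(self) -> tuple[str, ...]:
        return self.names if self.names is not None else _default_names(self.n_genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.edges)

    def has_edge(self, parent: int, child: int) -> bool:
        return (parent, child) in self.edges

    def out_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=int)
        for a, _ in self.edges:
            deg[a] += 1
        return deg

    def in_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=int)
        for _, b in self.edges:
            deg[b] += 1
        return deg

    def total_degree(self) -> np.ndarray:
        return self.in_degree() + self.out_degree()

    def parents(self, gene: int, sign: int | None = None) -> list[int]:
        """Regulators of ``gene``; optionally restricted to one sign."""
        return sorted(
            a for (a, b), s in self.edges.items()
            if b == gene and (sign is None or s == sign)
        )

    def children(self, gene: int) -> list[int]:
        return sorted(b for (a, b) in self.edges if a == gene)

    # -- transforms ------------------------------------------------------
    def reversed(self) -> "GeneNetwork":
        """Flip the direction of every edge, preserving signs and weights."""
        return GeneNetwork(
            n_genes=self.n_genes,
            edges={(b, a): s for (a, b), s in self.edges.items()},
            weights=None if self.weights is None
            else {(b, a): w for (a, b), w in self.weights.items()},
            names=self.names,
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_genes))
        for (a, b), s in self.edges.items():
            w = None if self.weights is None else self.weights.get((a, b))
            g.add_edge(a, b, sign=s, weight=w)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return (
            self.n_genes == other.n_genes
            and self.edges == other.edges
            and self.weights == other.weights
        )


@dataclass(frozen=True)
class TopologyConfig:
    """Parameters of the scale-free ground-truth generator.

    ``k_av`` is the target average *total* degree (in + out), so the edge
    count is ``round(k_av * n_genes / 2)``.  ``r`` is the descriptive
    power-law exponent of the intended degree distribution; it documents the
    target regime and is not enforced during generation.  ``p_pos`` is the
    probability that an edge is activatory.
    """

    n_genes: int
    k_av: float = 3.0
    r: float = 0.65
    p_pos: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.k_av < 0:
            raise ValueError("k_av must be >= 0")
        if not 0.0 <= self.p_pos <= 1.0:
            raise ValueError("p_pos must lie in [0, 1]")

    @property
    def n_edges(self) -> int:
        return int(round(self.k_av * self.n_genes / 2.0))


def generate_scale_free(config: TopologyConfig) -> GeneNetwork:
    """Grow a scale-free directed signed network by preferential attachment.

    Each node ``i`` receives an initial score ``u_i ~ U[0,1]``.  Ordered
    pairs ``(a, b)`` are drawn uniformly (no self-pairs); the candidate edge
    ``a -> b`` is accepted iff both attachment probabilities
    ``P_i = (u_i + k_i) / max_j(u_j + k_j)`` (``k_i`` = current total degree)
    exceed fresh uniform thresholds.  Growth stops at the target edge count
    ``round(k_av * n_genes / 2)``; signs are then assigned with probability
    ``p_pos`` of activation.

    Raises
    ------
    ImpossibleTopologyError
        If the target edge count exceeds ``n_genes * (n_genes - 1)`` or a
        positive edge count is requested on fewer than two nodes.
    """
    n = config.n_genes
    target = config.n_edges
    if target > 0 and n < 2:
        raise ImpossibleTopologyError(
            f"cannot place {target} edges on {n} node(s)"
        )
    if target > n * (n - 1):
        raise ImpossibleTopologyError(
            f"target edge count {target} exceeds maximum {n * (n - 1)} "
            f"for {n} nodes"
        )
    rng = np.random.default_rng(config.seed)
    u = rng.random(n)
    k = np.zeros(n)
    edges: dict[tuple[int, int], int] = {}
    max_attempts = 10_000 + 2_000 * max(target, 1)
    attempts = 0
    while len(edges) < target:
        attempts += 1
        if attempts > max_attempts:
            raise ImpossibleTopologyError(
                f"generator stalled at {len(edges)}/{target} edges "
                f"after {attempts} attempts"
            )
        a = int(rng.integers(n))
        b = int(rng.integers(n - 1))
        if b >= a:
            b += 1
        if (a, b) in edges:
            continue
        scores = u + k
        p = scores / scores.max()
        t1, t2 = rng.random(2)
        if p[a] >= t1 and p[b] >= t2:
            edges[(a, b)] = 0
            k[a] += 1
            k[b] += 1
    net = GeneNetwork(n_genes=n, edges=edges)
    return assign_signs(net, config.p_pos, seed=int(rng.integers(2**31)))


def assign_signs(network: GeneNetwork, p_pos: float, seed: int) -> GeneNetwork:
    """Return a copy with each edge activatory with probability ``p_pos``.

    A fresh uniform draw per edge (in sorted edge order, so the assignment is
    reproducible) decides the sign: +1 with probability ``p_pos``, else -1.
    """
    if not 0.0 <= p_pos <= 1.0:
        raise ValueError("p_pos must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = {}
    for pair in sorted(network.edges):
        edges[pair] = 1 if rng.random() < p_pos else -1
    return GeneNetwork(
        n_genes=network.n_genes, edges=edges,
        weights=network.weights, names=network.names,
    )


def random_uniform_network(
    n_genes: int, n_edges: int, seed: int, p_pos: float = 0.5
) -> GeneNetwork:
    """Uniform-random directed network (Erdős–Rényi with fixed edge count).

    Degree-matched null model used as a comparison oracle for the
    heavy-tailed degree distribution of :func:`generate_scale_free`; not a
    simulation topology in its own right.
    """
    if n_edges > n_genes * (n_genes - 1):
        raise ImpossibleTopologyError("too many edges requested")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[int, int], int] = {}
    while len(edges) < n_edges:
        a = int(rng.integers(n_genes))
        b = int(rng.integers(n_genes - 1))
        if b >= a:
            b += 1
        edges.setdefault((a, b), 0)
    net = GeneNetwork(n_genes=n_genes, edges=edges)
    return assign_signs(net, p_pos, seed=int(rng.integers(2**31)))
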