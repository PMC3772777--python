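"""Core directed-graph representation and structural primitives.

Graphs are stored as dense adjacency matrices with the convention that
rows are outputs and columns are inputs: ``adj[i, j] = 1`` means there is
a directed edge ``i -> j``.  Self-loops are structurally forbidden (the
diagonal must be zero), matching the population of networks this package
analyzes.  Node indices are 0-based internally; human-facing I/O (edge
lists, CLI output) is 1-based.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "BinaryDigraph",
    "DegreeProfile",
    "ReachabilityMatrix",
    "degrees",
    "density",
    "reachability_matrix",
    "is_weakly_connected",
    "are_isomorphic",
    "canonical_key",
    "to_igraph",
]


@dataclasses.dataclass(frozen=True)
class BinaryDigraph:
    """A directed, unweighted graph without self-loops.

    Parameters
    ----------
    adj
        Square 0/1 matrix; ``adj[i, j] = 1`` encodes the edge ``i -> j``.
    """

    adj: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adj)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 1:
            raise ValueError(f"adjacency must be square and non-empty, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be exactly 0 or 1")
        if np.diagonal(a).any():
            raise ValueError("self-loops are not allowed (diagonal must be zero)")
        a = a.astype(np.int8, copy=True)
        a.setflags(write=False)
        object.__setattr__(self, "adj", a)

    @property
    def n(self) -> int:
        return self.adj.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adj.sum())

    def edges(self) -> list[tuple[int, int]]:
        """Edge list as 0-based ``(source, target)`` pairs."""
        src, dst = np.nonzero(self.adj)
        return list(zip(src.tolist(), dst.tolist()))

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]], *, one_based: bool = False) -> "BinaryDigraph":
        off = 1 if one_based else 0
        adj = np.zeros((n, n), dtype=np.int8)
        for s, t in edges:
            adj[s - off, t - off] = 1
        return cls(adj)

    def complement(self) -> "BinaryDigraph":
        """Off-diagonal complement (edge present iff absent here)."""
        adj = 1 - self.adj
        np.fill_diagonal(adj, 0)
        return BinaryDigraph(adj)

    def transpose(self) -> "BinaryDigraph":
        return BinaryDigraph(self.adj.T)

    def relabel(self, perm: Sequence[int]) -> "BinaryDigraph":
        """Relabel nodes so that old node ``i`` becomes ``perm[i]``."""
        p = np.asarray(perm)
        adj = np.zeros_like(self.adj)
        adj[np.ix_(p, p)] = self.adj
        return BinaryDigraph(adj)


@dataclasses.dataclass(frozen=True)
class DegreeProfile:
    """Per-node in-degree (column sums) and out-degree (row sums)."""

    in_deg: np.ndarray
    out_deg: np.ndarray


@dataclasses.dataclass(frozen=True)
class ReachabilityMatrix:
    """Transitive closure; ``reach[i, j] = 1`` iff a path of length >= 1 runs i -> j."""

    reach: np.ndarray


def degrees(G: BinaryDigraph) -> DegreeProfile:
    """In-degree (inputs per column) and out-degree (outputs per row) of every node."""
    a = G.adj
    return DegreeProfile(in_deg=a.sum(axis=0).astype(np.int64), out_deg=a.sum(axis=1).astype(np.int64))


def density(G: BinaryDigraph) -> float:
    """Fraction of realizable connections present: edges / (n^2 - n).

    Self-loops are excluded from the denominator because they are
    structurally impossible in this graph class.
    """
    if G.n < 2:
        raise ValueError("density requires at least 2 nodes")
    return G.edge_count / (G.n * G.n - G.n)


def reachability_matrix(G: BinaryDigraph, *, cycle_diagonal: bool = True) -> ReachabilityMatrix:
    """Transitive closure of the adjacency matrix (paths of length >= 1).

    With ``cycle_diagonal`` (default) the diagonal entry ``reach[i, i]`` is 1
    exactly when node ``i`` lies on a directed cycle; with the flag off the
    diagonal is forced to zero.
    """
    r = G.adj.astype(bool)
    while True:
        r2 = r | (r @ r)
        if (r2 == r).all():
            break
        r = r2
    out = r.astype(np.int8)
    if not cycle_diagonal:
        np.fill_diagonal(out, 0)
    return ReachabilityMatrix(reach=out)


def is_weakly_connected(G: BinaryDigraph) -> bool:
    """True iff every node pair is joined by a path in the symmetrized graph."""
    if G.n == 1:
        return True
    ncomp, _ = connected_components(csr_matrix(G.adj), directed=True, connection="weak")
    return ncomp == 1


def to_igraph(G: BinaryDigraph) -> ig.Graph:
    g = ig.Graph(n=G.n, edges=G.edges(), directed=True)
    return g


def are_isomorphic(G1: BinaryDigraph, G2: BinaryDigraph) -> bool:
    """Directed graph isomorphism (exact, VF2 after cheap invariant screens)."""
    if G1.n != G2.n or G1.edge_count != G2.edge_count:
        return False
    d1, d2 = degrees(G1), degrees(G2)
    pairs1 = sorted(zip(d1.in_deg.tolist(), d1.out_deg.tolist()))
    pairs2 = sorted(zip(d2.in_deg.tolist(), d2.out_deg.tolist()))
    if pairs1 != pairs2:
        return False
    return to_igraph(G1).isomorphic_vf2(to_igraph(G2))


def canonical_key(G: BinaryDigraph) -> bytes:
    """Canonical-form hash key: equal keys iff graphs are isomorphic."""
    g = to_igraph(G)
    perm = g.canonical_permutation()
    canon = g.permute_vertices(perm)
    edges = sorted(canon.get_edgelist())
    return np.array([G.n] + [x for e in edges for x in e], dtype=np.int32).tobytes()
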