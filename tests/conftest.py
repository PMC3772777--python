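"""Shared fixtures and independent brute-force oracles.

The oracles here (breadth-first reachability, permutation-based
isomorphism, exhaustive motif classification) deliberately avoid the
library code paths they validate.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sdnet.graph_model import BinaryDigraph


def random_digraph(rng: np.random.Generator, n: int, p: float) -> BinaryDigraph:
    adj = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryDigraph(adj)


def bfs_reachability(adj: np.ndarray) -> np.ndarray:
    """Reachability by explicit breadth-first search from every node (paths >= 1)."""
    n = adj.shape[0]
    reach = np.zeros((n, n), dtype=np.int8)
    for s in range(n):
        frontier = [t for t in range(n) if adj[s, t]]
        seen = set(frontier)
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        for t in seen:
            reach[s, t] = 1
    return reach


def brute_isomorphic(a1: np.ndarray, a2: np.ndarray) -> bool:
    """Isomorphism by trying every vertex permutation."""
    n = a1.shape[0]
    if a2.shape[0] != n:
        return False
    for perm in itertools.permutations(range(n)):
        p = list(perm)
        if (a1[np.ix_(p, p)] == a2).all():
            return True
    return False


def undirected_connected(adj: np.ndarray) -> bool:
    """Weak connectivity by union-find on the symmetrized edge set."""
    n = adj.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)}) == 1


def brute_motif_counts(adj: np.ndarray, size: int) -> list[int]:
    """Counts of weakly connected induced subgraphs per isomorphism class.

    Classes are discovered on the fly by pairwise permutation
    isomorphism; returned as a sorted count list (class order is
    arbitrary, so comparisons use the multiset).
    """
    n = adj.shape[0]
    reps: list[np.ndarray] = []
    counts: list[int] = []
    for combo in itertools.combinations(range(n), size):
        sub = adj[np.ix_(combo, combo)]
        if not sub.any() or not undirected_connected(sub):
            continue
        for i, rep in enumerate(reps):
            if brute_isomorphic(sub, rep):
                counts[i] += 1
                break
        else:
            reps.append(sub)
            counts.append(1)
    return sorted(counts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120624)


@pytest.fixture
def chain3() -> BinaryDigraph:
    return BinaryDigraph.from_edges(3, [(1, 2), (2, 3)], one_based=True)


@pytest.fixture
def cycle4() -> BinaryDigraph:
    return BinaryDigraph.from_edges(4, [(1, 2), (2, 3), (3, 4), (4, 1)], one_based=True)


def complete_digraph(n: int) -> BinaryDigraph:
    return BinaryDigraph(np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8))


def empty_digraph(n: int) -> BinaryDigraph:
    return BinaryDigraph(np.zeros((n, n), dtype=np.int8))
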