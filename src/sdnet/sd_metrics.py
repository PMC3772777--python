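"""System Difference (SD) and Average Connectedness (AC).

SD is a Jaccardian measure of node specialization: for every unordered
pair of nodes it counts the non-overlap (symmetric-difference size) of
their output sets and of their input sets, and averages over the
n(n-1)/2 pairs.  Algebraically this collapses to a quadratic function of
the degree sequence,

    SD = sum_t [ in(t)(n - in(t)) + out(t)(n - out(t)) ] / (n(n-1)/2),

so SD reads only the degree distribution: it is maximal when every in-
and out-degree sits at n/2 and zero for the empty graph.  AC is the mean
of the transitive reachability matrix, sum(R)/n^2 — the fraction of
ordered node pairs (a, b) such that b is reachable from a.

Both measures are weight-blind: weighted matrices are binarized
(nonzero -> edge) before computation, so column normalization never
changes SD or AC.  Numerators are accumulated in exact integer
arithmetic; the single division happens last.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .graph_model import BinaryDigraph, degrees, reachability_matrix

__all__ = [
    "NodeConnectionSets",
    "non_overlap",
    "node_connection_sets",
    "sd_set_form",
    "sd_degree_form",
    "sd_numerator_set_form",
    "sd_numerator_degree_form",
    "sd_node",
    "average_connectedness",
    "as_binary",
]


@dataclasses.dataclass(frozen=True)
class NodeConnectionSets:
    """Out(x): successor set of each node; In(x): predecessor set."""

    out_sets: tuple[frozenset[int], ...]
    in_sets: tuple[frozenset[int], ...]


def as_binary(G) -> BinaryDigraph:
    """Binarized view of a graph: any positive weight counts as an edge."""
    if isinstance(G, BinaryDigraph):
        return G
    w = np.asarray(getattr(G, "weights", G))
    return BinaryDigraph((w > 0).astype(np.int8))


def non_overlap(set_a: frozenset | set, set_b: frozenset | set) -> int:
    """Number of distinct elements between two sets: |A ∪ B| - |A ∩ B|."""
    return len(set(set_a) ^ set(set_b))


def node_connection_sets(G) -> NodeConnectionSets:
    a = as_binary(G).adj
    out_sets = tuple(frozenset(np.nonzero(a[i])[0].tolist()) for i in range(a.shape[0]))
    in_sets = tuple(frozenset(np.nonzero(a[:, j])[0].tolist()) for j in range(a.shape[1]))
    return NodeConnectionSets(out_sets=out_sets, in_sets=in_sets)


def sd_numerator_set_form(G) -> int:
    """Exact integer numerator of SD from pairwise set comparisons."""
    G = as_binary(G)
    if G.n < 2:
        raise ValueError("SD requires at least 2 nodes")
    sets = node_connection_sets(G)
    n = G.n
    total = 0
    for a in range(n):
        for b in range(a + 1, n):
            total += non_overlap(sets.out_sets[a], sets.out_sets[b])
            total += non_overlap(sets.in_sets[a], sets.in_sets[b])
    return total


def sd_numerator_degree_form(G) -> int:
    """Exact integer numerator of SD from the degree sequence."""
    G = as_binary(G)
    if G.n < 2:
        raise ValueError("SD requires at least 2 nodes")
    d = degrees(G)
    n = G.n
    in_d = d.in_deg.astype(object)
    out_d = d.out_deg.astype(object)
    return int(sum(in_d * (n - in_d) + out_d * (n - out_d)))


def sd_set_form(G) -> float:
    """SD via explicit pairwise non-overlap of input and output sets."""
    G = as_binary(G)
    return sd_numerator_set_form(G) / (G.n * (G.n - 1) // 2)


def sd_degree_form(G) -> float:
    """SD via the degree-sequence formula; equals :func:`sd_set_form` exactly."""
    G = as_binary(G)
    return sd_numerator_degree_form(G) / (G.n * (G.n - 1) // 2)


def sd_node(G, t: int, *, normalized: bool = False) -> float:
    """Single-node SD contribution in(t)(n-in(t)) + out(t)(n-out(t)).

    With ``normalized`` the contribution is divided by the graph-level
    denominator n(n-1)/2, so the normalized values sum to SD.
    """
    G = as_binary(G)
    if not 0 <= t < G.n:
        raise IndexError(f"node id {t} out of range for n={G.n}")
    d = degrees(G)
    n = G.n
    val = int(d.in_deg[t]) * (n - int(d.in_deg[t])) + int(d.out_deg[t]) * (n - int(d.out_deg[t]))
    if normalized:
        return val / (n * (n - 1) // 2)
    return float(val)


def average_connectedness(G) -> float:
    """AC: mean of the reachability matrix, sum(R)/n^2, in [0, 1]."""
    G = as_binary(G)
    r = reachability_matrix(G).reach
    return float(r.sum()) / (G.n * G.n)
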