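"""Comparison graph metrics: degree, cliques, path length, motif census.

Cliques are detected on the OR-symmetrized undirected graph (an edge in
either direction makes an undirected edge).  Average path length is the
mean directed geodesic distance over ordered pairs for which a path
exists; unreachable pairs are excluded by default.  Motif counting uses
induced subgraphs and tallies only weakly connected isomorphism classes;
for three nodes there are exactly 13 such classes.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from functools import lru_cache

import igraph as ig
import numpy as np

from .graph_model import BinaryDigraph, canonical_key, degrees, to_igraph

__all__ = [
    "MotifCensus",
    "CliqueSummary",
    "max_total_degree",
    "clique_summary",
    "average_path_length",
    "motif_census",
    "motif_classes",
    "motif_density_group",
    "enumerate_motif_classes",
]


@dataclasses.dataclass(frozen=True)
class MotifCensus:
    """Counts of weakly connected induced subgraphs by isomorphism class.

    ``class_counts`` maps the graph library's isomorphism-class id of
    each weakly connected motif class to its count; ``motif_number`` is
    their sum.  Disconnected classes are tallied in ``disconnected``.
    """

    size: int
    class_counts: dict[int, int]
    motif_number: int
    disconnected: int | None


@dataclasses.dataclass(frozen=True)
class CliqueSummary:
    omega: int
    n_maximal: int
    avg_maximal_size: float


def max_total_degree(G: BinaryDigraph) -> int:
    """Maximum over nodes of in-degree + out-degree."""
    d = degrees(G)
    return int((d.in_deg + d.out_deg).max())


def clique_summary(G: BinaryDigraph) -> CliqueSummary:
    """Maximal cliques of the OR-symmetrized graph (Bron-Kerbosch)."""
    u = to_igraph(G).as_undirected(mode="collapse")
    cliques = u.maximal_cliques()
    sizes = [len(c) for c in cliques]
    return CliqueSummary(
        omega=int(max(sizes)) if sizes else 0,
        n_maximal=len(sizes),
        avg_maximal_size=float(np.mean(sizes)) if sizes else float("nan"),
    )


def average_path_length(G: BinaryDigraph, *, strict: bool = False) -> float:
    """Mean directed geodesic distance over reachable ordered pairs.

    Unreachable pairs are excluded from the mean unless ``strict``, in
    which case any unreachable pair raises.  A graph with no edges has
    no reachable pair and returns NaN with a warning.
    """
    g = to_igraph(G)
    if strict and G.n > 1:
        sp = np.array(g.distances(mode="out"), dtype=float)
        off = ~np.eye(G.n, dtype=bool)
        if np.isinf(sp[off]).any():
            raise ValueError("graph contains unreachable ordered pairs (strict mode)")
    if G.edge_count == 0:
        warnings.warn("average path length undefined for an edgeless graph", stacklevel=2)
        return float("nan")
    return float(g.average_path_length(directed=True, unconn=True))


@lru_cache(maxsize=None)
def _isoclass_table(size: int) -> tuple[tuple[int, ...], dict[int, int]]:
    """(weakly connected isoclass ids, isoclass id -> edge count)."""
    n_classes = {3: 16, 4: 218}[size]
    connected = []
    edge_counts = {}
    for cid in range(n_classes):
        h = ig.Graph.Isoclass(size, cid, directed=True)
        edge_counts[cid] = h.ecount()
        if h.is_connected(mode="weak"):
            connected.append(cid)
    return tuple(connected), edge_counts


def motif_classes(size: int) -> tuple[int, ...]:
    """Isomorphism-class ids of the weakly connected motifs of a given size."""
    if size not in (3, 4):
        raise ValueError("motif size must be 3 or 4")
    return _isoclass_table(size)[0]


def motif_census(G: BinaryDigraph, size: int, *, tally_disconnected: bool = False) -> MotifCensus:
    """Classify every weakly connected induced ``size``-node subgraph.

    With ``tally_disconnected`` the count of induced subgraphs that
    contain edges but are not weakly connected is also reported (an
    O(C(n, size)) scan, so off by default).
    """
    if size not in (3, 4):
        raise ValueError("motif size must be 3 or 4")
    if G.n < size:
        raise ValueError(f"graph has {G.n} nodes, need at least {size}")
    counts = to_igraph(G).motifs_randesu(size=size)
    connected, _ = _isoclass_table(size)
    class_counts = {cid: int(counts[cid]) for cid in connected}
    motif_number = int(sum(class_counts.values()))
    disconnected = None
    if tally_disconnected:
        nonempty = sum(
            1
            for combo in itertools.combinations(range(G.n), size)
            if G.adj[np.ix_(combo, combo)].any()
        )
        disconnected = nonempty - motif_number
    return MotifCensus(size=size, class_counts=class_counts, motif_number=motif_number, disconnected=disconnected)


def motif_density_group(class_id: int, size: int = 3) -> int:
    """Density group (1-4) of a weakly connected 3-node motif class.

    Grouping is by motif edge count: {2, 4} -> 1 (densities 1/3 and 2/3,
    equidistant from 0.5), {3} -> 2 (density 0.5), {5} -> 3, {6} -> 4.
    """
    if size != 3:
        raise ValueError("density groups are defined for size-3 motifs only")
    connected, edge_counts = _isoclass_table(3)
    if class_id not in connected:
        raise ValueError(f"class {class_id} is not a weakly connected 3-node motif class")
    e = edge_counts[class_id]
    return {2: 1, 3: 2, 4: 1, 5: 3, 6: 4}[e]


def enumerate_motif_classes(size: int) -> list[BinaryDigraph]:
    """Exhaustively enumerate weakly connected digraph isomorphism classes.

    Every labeled self-loop-free digraph on ``size`` nodes is generated,
    non-weakly-connected ones dropped, and one representative kept per
    isomorphism class (canonical-form deduplication).  For size 3 this
    yields exactly 13 representatives.
    """
    from .graph_model import is_weakly_connected

    cells = [(i, j) for i in range(size) for j in range(size) if i != j]
    reps: dict[bytes, BinaryDigraph] = {}
    for bits in itertools.product((0, 1), repeat=len(cells)):
        adj = np.zeros((size, size), dtype=np.int8)
        for (i, j), b in zip(cells, bits):
            adj[i, j] = b
        g = BinaryDigraph(adj)
        if not is_weakly_connected(g):
            continue
        key = canonical_key(g)
        if key not in reps:
            reps[key] = g
    return list(reps.values())
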