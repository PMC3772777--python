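"""Graph file formats, run configuration and result writing.

Supported graph formats:

* adjacency CSV/TSV — n header-less rows of n comma/tab-separated
  values, row = source node;
* edge list TSV — two columns ``source<TAB>target``, 1-based node ids;
* GraphML — interchange with standard graph tools (via igraph).

Files with any weight outside {0, 1} load as :class:`WeightedDigraph`,
otherwise as :class:`BinaryDigraph`.  A nonzero diagonal is always a
format error: the graph populations here never contain self-loops.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Any

import igraph as ig
import numpy as np
import pandas as pd
import yaml

from .graph_model import BinaryDigraph
from .generators import WeightedDigraph

__all__ = [
    "GraphFormatError",
    "RunConfig",
    "read_graph",
    "write_graph",
    "write_results",
]


class GraphFormatError(ValueError):
    """A graph file violates the expected format."""


@dataclasses.dataclass
class RunConfig:
    """Serializable record of everything that determines a run."""

    command: str
    seed: int = 0
    generator: dict[str, Any] = dataclasses.field(default_factory=dict)
    metrics: list[str] = dataclasses.field(default_factory=list)
    phi: dict[str, Any] = dataclasses.field(default_factory=dict)
    outdir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | os.PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _matrix_to_graph(w: np.ndarray, source: str) -> BinaryDigraph | WeightedDigraph:
    if w.shape[0] != w.shape[1]:
        raise GraphFormatError(f"{source}: matrix is {w.shape[0]}x{w.shape[1]}, expected square")
    diag = np.nonzero(np.diagonal(w))[0]
    if diag.size:
        raise GraphFormatError(f"{source}: self-loop on node {diag[0] + 1} (nonzero diagonal)")
    if (w < 0).any():
        raise GraphFormatError(f"{source}: negative weights are not allowed")
    if np.isin(w, (0.0, 1.0)).all():
        return BinaryDigraph(w.astype(np.int8))
    return WeightedDigraph(w)


def _read_adjacency(path: Path, sep: str) -> BinaryDigraph | WeightedDigraph:
    rows = []
    width = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            row = [float(x) for x in line.strip().split(sep)]
        except ValueError as exc:
            raise GraphFormatError(f"{path}:{ln}: unparseable value ({exc})") from exc
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise GraphFormatError(f"{path}:{ln}: ragged row ({len(row)} values, expected {width})")
        rows.append(row)
    if not rows:
        raise GraphFormatError(f"{path}: empty file")
    return _matrix_to_graph(np.array(rows), str(path))


def _read_edgelist(path: Path) -> BinaryDigraph:
    edges = []
    max_node = 0
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphFormatError(f"{path}:{ln}: expected 'source<TAB>target', got {line!r}")
        try:
            s, t = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise GraphFormatError(f"{path}:{ln}: non-integer node id") from exc
        if s < 1 or t < 1:
            raise GraphFormatError(f"{path}:{ln}: node ids are 1-based, got {s}, {t}")
        if s == t:
            raise GraphFormatError(f"{path}:{ln}: self-loop on node {s}")
        edges.append((s, t))
        max_node = max(max_node, s, t)
    if not edges:
        raise GraphFormatError(f"{path}: no edges")
    return BinaryDigraph.from_edges(max_node, edges, one_based=True)


def _read_graphml(path: Path) -> BinaryDigraph | WeightedDigraph:
    g = ig.Graph.Read_GraphML(str(path))
    if not g.is_directed():
        raise GraphFormatError(f"{path}: graph is undirected")
    w = np.zeros((g.vcount(), g.vcount()))
    weights = g.es["weight"] if "weight" in g.es.attributes() else [1.0] * g.ecount()
    for e, wt in zip(g.es, weights):
        w[e.source, e.target] = wt
    return _matrix_to_graph(w, str(path))


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext == ".graphml":
        return "graphml"
    if ext in (".edges", ".edgelist"):
        return "edgelist"
    if ext in (".csv", ".txt"):
        return "adjacency_csv"
    if ext == ".tsv":
        return "adjacency_tsv"
    raise GraphFormatError(f"{path}: cannot infer format from extension {ext!r}")


def read_graph(path: str | os.PathLike, fmt: str = "auto") -> BinaryDigraph | WeightedDigraph:
    """Load a directed graph; format chosen by extension unless given."""
    p = Path(path)
    if not p.exists():
        raise GraphFormatError(f"{p}: file not found")
    if fmt == "auto":
        fmt = _detect_format(p)
    if fmt == "adjacency_csv":
        return _read_adjacency(p, ",")
    if fmt == "adjacency_tsv":
        return _read_adjacency(p, "\t")
    if fmt == "edgelist":
        return _read_edgelist(p)
    if fmt == "graphml":
        return _read_graphml(p)
    raise GraphFormatError(f"unknown format {fmt!r}")


def write_graph(G: BinaryDigraph | WeightedDigraph, path: str | os.PathLike, fmt: str = "auto") -> None:
    p = Path(path)
    if fmt == "auto":
        fmt = _detect_format(p)
    w = G.adj if isinstance(G, BinaryDigraph) else G.weights
    if fmt in ("adjacency_csv", "adjacency_tsv"):
        sep = "," if fmt == "adjacency_csv" else "\t"
        fmt_cell = (lambda x: str(int(x))) if isinstance(G, BinaryDigraph) else (lambda x: repr(float(x)))
        p.write_text("\n".join(sep.join(fmt_cell(x) for x in row) for row in w) + "\n")
    elif fmt == "edgelist":
        src, dst = np.nonzero(w)
        p.write_text("".join(f"{s + 1}\t{t + 1}\n" for s, t in zip(src, dst)))
    elif fmt == "graphml":
        g = ig.Graph(n=w.shape[0], edges=list(zip(*np.nonzero(w))), directed=True)
        g.es["weight"] = [float(w[s, t]) for s, t in g.get_edgelist()]
        g.write_graphml(str(p))
    else:
        raise GraphFormatError(f"unknown format {fmt!r}")


def write_results(
    records: pd.DataFrame,
    fits: pd.DataFrame | None,
    manifest: dict[str, Any],
    outdir: str | os.PathLike,
) -> dict[str, Path]:
    """Write records.csv, fits.csv and manifest.json with deterministic layout."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["records"] = out / "records.csv"
    records.to_csv(paths["records"], index=False)
    if fits is not None:
        paths["fits"] = out / "fits.csv"
        fits.to_csv(paths["fits"], index=False)
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return paths
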