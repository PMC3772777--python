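"""Random weakly-connected digraph generators with rejection filtering.

Three generation schemes populate the experiments:

``bernoulli``
    Every off-diagonal cell independently receives weight 0.5 with
    probability ``p`` (default 0.5).
``fixed_column``
    One column fill ``c`` is drawn uniformly from {1, ..., n-1} per
    matrix; every column then gets exactly ``c`` nonzero entries placed
    uniformly among its n-1 off-diagonal cells, each of weight ``k/c``.
    The output is simultaneously binary-patterned and column-normalized
    (every column sums to ``k``), so C = A.
``uniform_density``
    A target density u ~ Uniform(0, 1) is drawn; distinct off-diagonal
    cells are added in a uniformly random order until the density
    reaches or just exceeds u.  Output is unweighted.

Candidates with self-loops cannot arise by construction; candidates
failing weak connectivity or duplicating (up to isomorphism) an earlier
accept within the same population are discarded and regenerated.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Union

import numpy as np

from .graph_model import BinaryDigraph, canonical_key, is_weakly_connected

__all__ = [
    "WeightedDigraph",
    "GeneratorConfig",
    "BudgetExhaustedError",
    "gen_bernoulli",
    "gen_fixed_column",
    "gen_uniform_density",
    "normalize",
    "binarize",
    "sample_population",
]

Scheme = Literal["bernoulli", "fixed_column", "uniform_density"]


@dataclasses.dataclass(frozen=True)
class WeightedDigraph:
    """Nonnegative weight matrix with zero diagonal (normalized connection matrix C)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] < 1:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.diagonal(w).any():
            raise ValueError("self-loops are not allowed (diagonal must be zero)")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


Graph = Union[BinaryDigraph, WeightedDigraph]


@dataclasses.dataclass
class GeneratorConfig:
    """Configuration of one population draw; fully determines the sample."""

    n: int
    scheme: Scheme = "fixed_column"
    p: float = 0.5
    k: float = 0.5
    seed: int = 0
    reject_isomorphs: bool = True
    require_weak_connectivity: bool = True
    max_attempts_per_graph: int = 1000

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if not 0 < self.k < 1:
            raise ValueError("normalization constant k must lie in (0, 1)")


class BudgetExhaustedError(RuntimeError):
    """Raised when rejection sampling cannot find another admissible graph."""


def binarize(W: Graph) -> BinaryDigraph:
    if isinstance(W, BinaryDigraph):
        return W
    return BinaryDigraph((W.weights > 0).astype(np.int8))


def normalize(A: Graph, k: float = 0.5) -> WeightedDigraph:
    """Column-normalize an adjacency pattern: C[i,j] = k*A[i,j]/colsum(j).

    Every nonzero column of the result sums to ``k``; zero columns stay
    zero (tolerated, since stationarity only needs column sums < 1).
    """
    if not 0 < k < 1:
        raise ValueError("k must lie in (0, 1)")
    a = binarize(A).adj.astype(float)
    colsum = a.sum(axis=0)
    scale = np.divide(k, colsum, out=np.zeros_like(colsum, dtype=float), where=colsum > 0)
    return WeightedDigraph(a * scale[np.newaxis, :])


def gen_bernoulli(n: int, p: float, rng: np.random.Generator) -> WeightedDigraph:
    """Each off-diagonal cell gets weight 0.5 with probability ``p``."""
    w = np.where(rng.random((n, n)) < p, 0.5, 0.0)
    np.fill_diagonal(w, 0.0)
    return WeightedDigraph(w)


def gen_fixed_column(n: int, k: float, rng: np.random.Generator) -> WeightedDigraph:
    """Fixed per-column fill c ~ U{1..n-1}, weight k/c; already normalized."""
    c = int(rng.integers(1, n))  # same c for every column of this matrix
    w = np.zeros((n, n))
    offdiag = [np.delete(np.arange(n), j) for j in range(n)]
    for j in range(n):
        rows = rng.choice(offdiag[j], size=c, replace=False)
        w[rows, j] = k / c
    return WeightedDigraph(w)


def gen_uniform_density(n: int, rng: np.random.Generator) -> BinaryDigraph:
    """Add edges in random order until a Uniform(0,1) density target is reached."""
    target = rng.random()
    m = n * n - n
    cells = np.array([(i, j) for i in range(n) for j in range(n) if i != j])
    order = rng.permutation(m)
    n_edges = 0
    adj = np.zeros((n, n), dtype=np.int8)
    for idx in order:
        i, j = cells[idx]
        adj[i, j] = 1
        n_edges += 1
        if n_edges / m >= target:
            break
    return BinaryDigraph(adj)


def _draw(cfg: GeneratorConfig, rng: np.random.Generator) -> Graph:
    if cfg.scheme == "bernoulli":
        return gen_bernoulli(cfg.n, cfg.p, rng)
    if cfg.scheme == "fixed_column":
        return gen_fixed_column(cfg.n, cfg.k, rng)
    if cfg.scheme == "uniform_density":
        return gen_uniform_density(cfg.n, rng)
    raise ValueError(f"unknown scheme {cfg.scheme!r}")


def sample_population(cfg: GeneratorConfig, count: int) -> list[Graph]:
    """Draw exactly ``count`` admissible graphs under ``cfg``.

    Admissible means weakly connected (if required) and pairwise
    non-isomorphic against all earlier accepts of this call (if
    ``reject_isomorphs``).  Deterministic given ``cfg.seed``.

    Raises
    ------
    BudgetExhaustedError
        If ``max_attempts_per_graph * count`` candidate draws do not
        yield ``count`` accepts (e.g. asking for more non-isomorphic
        graphs than exist at small n).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    budget = cfg.max_attempts_per_graph * count
    accepted: list[Graph] = []
    seen: set[bytes] = set()
    attempts = 0
    while len(accepted) < count:
        if attempts >= budget:
            raise BudgetExhaustedError(
                f"accepted {len(accepted)}/{count} graphs after {attempts} attempts "
                f"(n={cfg.n}, scheme={cfg.scheme}); the requested population may not exist"
            )
        attempts += 1
        g = _draw(cfg, rng)
        b = binarize(g)
        if cfg.require_weak_connectivity and not is_weakly_connected(b):
            continue
        if cfg.reject_isomorphs:
            key = canonical_key(b)
            if key in seen:
                continue
            seen.add(key)
        accepted.append(g)
    return accepted
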