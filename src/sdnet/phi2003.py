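"""The 2003 integrated-information measure (Phi) for linear Gaussian systems.

A system of n units with normalized connection matrix CON evolves under
row-vector dynamics

    F = F . CON + C * R,

where R is unit-variance white Gaussian noise and C a per-unit noise
magnitude.  The stationary activity covariance is obtained with the
historical analytical shortcut of the original reference implementation,

    Q = (I - CON)^{-1},        COV = Q^T diag(C^2) Q,

which treats the recursion as a simultaneous equation.  That derivation
was later shown to be erroneous (the true stationary covariance solves a
discrete Lyapunov equation), but the correlation analyses this package
replicates were produced with it, so it is the default here
(``mode="reference"``); the
corrected Lyapunov solution is available as ``mode="corrected"`` for
sensitivity analysis.

Effective information from part A to part B of a subset is the Gaussian
mutual information MI(A:B) when A is driven by maximum-variance
perturbation noise (magnitude ``c_p``) while B keeps its tiny intrinsic
noise (``c_i``):

    EI(A->B) = MI(A_Hmax : B),    EI(A<->B) = EI(A->B) + EI(B->A).

The minimum information bipartition (MIB) of a subset minimizes
EI(A<->B) / min{Hmax(A), Hmax(B)}; Phi of the subset is the
*unnormalized* EI at the MIB, and the system's Phi is the maximum over
all subsets of size >= 2.  All entropies are in nats; determinants are
evaluated in log space (the intrinsic noise c_i = 1e-5 makes raw
determinants underflow).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from ._masks import gather_submatrices, mask_tables

__all__ = [
    "LinearGaussianSystem",
    "Bipartition",
    "PhiResult",
    "ComputeCapError",
    "stationary_covariance",
    "gaussian_entropy",
    "mutual_information",
    "effective_information",
    "minimum_information_bipartition",
    "system_phi",
]

LOG_2PIE = math.log(2.0 * math.pi * math.e)


class ComputeCapError(RuntimeError):
    """Raised when a subset search would exceed the configured size cap."""


@dataclasses.dataclass(frozen=True)
class LinearGaussianSystem:
    """Normalized connection matrix plus perturbation/intrinsic noise magnitudes."""

    con: np.ndarray
    c_p: float = 1.0
    c_i: float = 1e-5

    def __post_init__(self) -> None:
        c = np.asarray(self.con, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("connection matrix must be square")
        rho = np.abs(np.linalg.eigvals(c)).max() if c.size else 0.0
        if rho >= 1.0:
            raise ValueError(f"spectral radius {rho:.4f} >= 1: system is not stationary")
        if self.c_p <= 0 or self.c_i <= 0:
            raise ValueError("noise magnitudes must be positive")
        c = c.copy()
        c.setflags(write=False)
        object.__setattr__(self, "con", c)

    @property
    def n(self) -> int:
        return self.con.shape[0]


@dataclasses.dataclass(frozen=True)
class Bipartition:
    part_a: tuple[int, ...]
    part_b: tuple[int, ...]


@dataclasses.dataclass(frozen=True)
class PhiResult:
    subset: tuple[int, ...]
    mib: Bipartition
    ei_unnormalized: float
    ei_normalized: float
    phi: float


def stationary_covariance(
    con: np.ndarray, noise: np.ndarray, mode: str = "reference"
) -> np.ndarray:
    """Stationary covariance of F = F.CON + noise*R.

    ``mode="reference"`` uses the historical closed form
    COV = Q^T diag(noise^2) Q with Q = (I - CON)^{-1}; ``"corrected"``
    solves the discrete Lyapunov equation of the actual temporal
    recursion.
    """
    con = np.asarray(con, dtype=float)
    noise = np.broadcast_to(np.asarray(noise, dtype=float), (con.shape[0],))
    d = np.diag(noise**2)
    if mode == "reference":
        eye_minus = np.eye(con.shape[0]) - con
        cond = np.linalg.cond(eye_minus)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"I - CON is numerically singular (condition number {cond:.3e})"
            )
        q = np.linalg.inv(eye_minus)
        return q.T @ d @ q
    if mode == "corrected":
        # row-vector recursion F_t = F_{t-1}.CON + e  <=>  x_t = CON^T x_{t-1} + e
        return solve_discrete_lyapunov(con.T, d)
    raise ValueError(f"unknown covariance mode {mode!r}")


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy 0.5*ln((2*pi*e)^n det cov) in nats (log-space det)."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        eig = np.linalg.eigvalsh(cov)
        raise np.linalg.LinAlgError(
            f"covariance is not positive definite (smallest eigenvalue {eig.min():.3e})"
        )
    return 0.5 * (cov.shape[0] * LOG_2PIE + logdet)


def mutual_information(cov: np.ndarray, a: Sequence[int], b: Sequence[int]) -> float:
    """MI(A:B) = H(A) + H(B) - H(A,B) from blocks of a joint covariance."""
    a = list(a)
    b = list(b)
    if set(a) & set(b):
        raise ValueError("A and B must be disjoint")
    ab = a + b
    return (
        gaussian_entropy(cov[np.ix_(a, a)])
        + gaussian_entropy(cov[np.ix_(b, b)])
        - gaussian_entropy(cov[np.ix_(ab, ab)])
    )


def _noise_vector(sys: LinearGaussianSystem, k: int, perturbed: Iterable[int]) -> np.ndarray:
    noise = np.full(k, sys.c_i)
    noise[list(perturbed)] = sys.c_p
    return noise


def effective_information(
    sys: LinearGaussianSystem,
    a: Sequence[int],
    b: Sequence[int],
    mode: str = "reference",
) -> float:
    """EI(A->B): perturb A with c_p, leave c_i on B, recompute COV, take MI.

    A and B must bipartition the subset under analysis; the subsystem is
    the connection submatrix on A u B, cut off from the rest.
    """
    a = sorted(a)
    b = sorted(b)
    subset = sorted(set(a) | set(b))
    if set(a) & set(b) or not a or not b:
        raise ValueError("A and B must be disjoint and nonempty")
    pos = {node: i for i, node in enumerate(subset)}
    con_sub = sys.con[np.ix_(subset, subset)]
    noise = _noise_vector(sys, len(subset), [pos[x] for x in a])
    cov = stationary_covariance(con_sub, noise, mode)
    return mutual_information(cov, [pos[x] for x in a], [pos[x] for x in b])


def _hmax_per_node(sys: LinearGaussianSystem) -> float:
    """Maximum entropy of one perturbed unit: 0.5*ln(2*pi*e*c_p^2)."""
    return 0.5 * (LOG_2PIE + 2.0 * math.log(sys.c_p))


def _bipartition_scan_reference(
    con_sub: np.ndarray, c_p: float, c_i: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MI(P : S\\P) under 'perturb P' noise, for every nonempty proper P.

    Returns (mi, ei, sizes): ``ei[m] = mi[m] + mi[complement(m)]`` is the
    bidirectional EI of the bipartition {P, S\\P}, indexed by bitmask.
    Covariances for all masks are built in one batch from the shared
    Q = (I - CON)^{-1}; the full-set log-determinant uses the closed form
    log det(Q^T D Q) = 2 log|det Q| + sum log c^2.
    """
    k = con_sub.shape[0]
    masks, bits, sizes, comp_pos, groups = mask_tables(k)
    eye_minus = np.eye(k) - con_sub
    sign, ld_im = np.linalg.slogdet(eye_minus)
    if sign <= 0:
        raise np.linalg.LinAlgError("I - CON has non-positive determinant")
    q = np.linalg.inv(eye_minus)
    ld_q = -ld_im
    c2 = np.where(bits, c_p * c_p, c_i * c_i)
    cov = np.einsum("bi,ij,il->bjl", c2, q, q, optimize=True)
    ld_full = 2.0 * ld_q + np.log(c2).sum(axis=1)
    ld_p = np.empty(len(masks))
    ld_pc = np.empty(len(masks))
    for sel, pidx, cidx in groups:
        ld_p[sel] = np.linalg.slogdet(gather_submatrices(cov, sel, pidx))[1]
        ld_pc[sel] = np.linalg.slogdet(gather_submatrices(cov, sel, cidx))[1]
    mi = 0.5 * (ld_p + ld_pc - ld_full)
    ei = mi + mi[comp_pos]
    return mi, ei, sizes


def _bipartition_scan_generic(
    con_sub: np.ndarray, c_p: float, c_i: float, mode: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-mask loop over stationary covariances; any covariance mode."""
    k = con_sub.shape[0]
    masks, bits, sizes, comp_pos, _ = mask_tables(k)
    mi = np.empty(len(masks))
    for b, row in enumerate(bits):
        p = np.nonzero(row)[0].tolist()
        pc = np.nonzero(~row)[0].tolist()
        noise = np.full(k, c_i)
        noise[p] = c_p
        cov = stationary_covariance(con_sub, noise, mode)
        mi[b] = mutual_information(cov, p, pc)
    ei = mi + mi[comp_pos]
    return mi, ei, sizes


def minimum_information_bipartition(
    sys: LinearGaussianSystem,
    subset: Sequence[int] | None = None,
    mode: str = "reference",
) -> PhiResult:
    """Find the MIB of a subset and its Phi (unnormalized EI at the MIB).

    All 2^(k-1) - 1 unordered bipartitions are scanned; the winner
    minimizes EI(A<->B)/min{Hmax(A), Hmax(B)}.  Ties are broken toward
    the lexicographically smallest part containing the subset's first
    node.
    """
    subset = tuple(range(sys.n)) if subset is None else tuple(sorted(subset))
    k = len(subset)
    if k < 2:
        raise ValueError("a bipartition needs a subset of size >= 2")
    con_sub = sys.con[np.ix_(subset, subset)]
    if mode == "reference":
        _, ei, sizes = _bipartition_scan_reference(con_sub, sys.c_p, sys.c_i)
    else:
        _, ei, sizes = _bipartition_scan_generic(con_sub, sys.c_p, sys.c_i, mode)
    _, bits, _, _, _ = mask_tables(k)
    hmax1 = _hmax_per_node(sys)
    norm = np.minimum(sizes, k - sizes) * hmax1
    ei_norm = ei / norm
    # each unordered bipartition once: part_a is the part holding position 0
    cand = np.nonzero(bits[:, 0])[0]
    vals = ei_norm[cand]
    best_val = vals.min()
    ties = cand[np.isclose(vals, best_val, rtol=1e-12, atol=0.0)]
    best = min(ties, key=lambda b: tuple(np.nonzero(bits[b])[0]))
    part_a = tuple(subset[i] for i in np.nonzero(bits[best])[0])
    part_b = tuple(subset[i] for i in np.nonzero(~bits[best])[0])
    return PhiResult(
        subset=subset,
        mib=Bipartition(part_a=part_a, part_b=part_b),
        ei_unnormalized=float(ei[best]),
        ei_normalized=float(ei_norm[best]),
        phi=float(ei[best]),
    )


def system_phi(
    sys: LinearGaussianSystem, mode: str = "reference", cap: int = 12
) -> PhiResult:
    """Phi of the system: maximum subset Phi over all subsets of size >= 2.

    The scan touches every subset and every bipartition of each subset
    (on the order of 3^n covariance evaluations), so systems larger than
    ``cap`` nodes are refused.
    """
    if sys.n > cap:
        raise ComputeCapError(
            f"subset search over n={sys.n} nodes needs ~3^{sys.n} ≈ "
            f"{3**sys.n:.2e} bipartition evaluations; cap is {cap} nodes"
        )
    if sys.n < 2:
        raise ValueError("system must have at least 2 nodes")
    best: PhiResult | None = None
    for size in range(2, sys.n + 1):
        for subset in itertools.combinations(range(sys.n), size):
            res = minimum_information_bipartition(sys, subset, mode)
            if best is None or res.phi > best.phi:
                best = res
    assert best is not None
    return best
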