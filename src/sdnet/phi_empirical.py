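"""Lag-based integrated information (Phi Empirical) for stationary Gaussian systems.

The generative model is a first-order linear autoregression under the
same row-vector convention as the 2003 measure,

    X_t = X_{t-1} . A1 + E_t,

with E_t zero-mean Gaussian noise of identity covariance (by default)
and spectral radius of A1 below one.  The stationary covariance S solves
the discrete Lyapunov equation of the recursion, and the lag-tau
cross-covariance is cov(X_{t-tau}, X_t) = S . A1^tau.

Effective information across a bipartition {M1, M2} at lag tau is

    EI = 1/2 log[ det S / det cov(X_{t-tau} | X_t) ]
         - sum_k 1/2 log[ det S_Mk / det cov(Mk_{t-tau} | Mk_t) ],

where each part's conditional covariance is the Schur complement of its
own marginal past/present joint.  The minimum information bipartition
minimizes EI / K with K = 1/2 log min_k[(2*pi*e)^{|Mk|} det S_Mk]; Phi
is the unnormalized EI at that cut.  All logs are natural (nats).

Phi can also be estimated from a simulated time series by plugging
sample covariances into the same formulas, which is how the analytic
route is validated.
"""

from __future__ import annotations

import dataclasses

from typing import Sequence

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from ._masks import gather_submatrices, mask_tables
from .phi2003 import Bipartition, ComputeCapError, LOG_2PIE

__all__ = [
    "GenerativeModel",
    "EmpiricalPhiResult",
    "PhiEmpiricalProfile",
    "stationary_cov",
    "lagged_cross_cov",
    "ei_empirical",
    "phi_empirical",
    "phi_empirical_profile",
    "simulate",
    "estimate_covariances",
    "phi_empirical_from_series",
]


@dataclasses.dataclass(frozen=True)
class GenerativeModel:
    """First-order autoregressive connectivity A1 with noise covariance (identity default)."""

    a1: np.ndarray
    noise_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a1, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("A1 must be square")
        rho = np.abs(np.linalg.eigvals(a)).max() if a.size else 0.0
        if rho >= 1.0:
            raise ValueError(f"spectral radius {rho:.4f} >= 1: system is not stationary")
        nc = np.eye(a.shape[0]) if self.noise_cov is None else np.asarray(self.noise_cov, dtype=float)
        if nc.shape != a.shape or not np.allclose(nc, nc.T):
            raise ValueError("noise covariance must be symmetric and match A1")
        if np.linalg.eigvalsh(nc).min() <= 0:
            raise ValueError("noise covariance must be positive definite")
        a = a.copy()
        a.setflags(write=False)
        nc = nc.copy()
        nc.setflags(write=False)
        object.__setattr__(self, "a1", a)
        object.__setattr__(self, "noise_cov", nc)

    @property
    def n(self) -> int:
        return self.a1.shape[0]


@dataclasses.dataclass(frozen=True)
class EmpiricalPhiResult:
    tau: int
    mib: Bipartition
    ei: float
    k_norm: float
    phi: float


@dataclasses.dataclass(frozen=True)
class PhiEmpiricalProfile:
    per_tau: dict[int, EmpiricalPhiResult]
    phi_sum: float


def stationary_cov(model: GenerativeModel) -> np.ndarray:
    """Stationary covariance: S = A1^T S A1 + noise_cov (column form of the recursion)."""
    return solve_discrete_lyapunov(model.a1.T, model.noise_cov)


def lagged_cross_cov(model: GenerativeModel, tau: int, sigma: np.ndarray | None = None) -> np.ndarray:
    """cov(X_{t-tau}, X_t) = S . A1^tau."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if sigma is None:
        sigma = stationary_cov(model)
    return sigma @ np.linalg.matrix_power(model.a1, tau)


def _logdet(m: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(m)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix has non-positive determinant")
    return float(ld)


def _temporal_term(sigma: np.ndarray, cross: np.ndarray) -> float:
    """0.5*log[det S / det cov(past|present)] for one (sub)system."""
    cond = sigma - cross @ np.linalg.solve(sigma, cross.T)
    return 0.5 * (_logdet(sigma) - _logdet(cond))


def _ei_from_covs(
    sigma: np.ndarray, cross: np.ndarray, m1: Sequence[int], m2: Sequence[int]
) -> tuple[float, float]:
    """(EI, K) across bipartition {m1, m2} from whole-system covariances."""
    m1 = sorted(m1)
    m2 = sorted(m2)
    if set(m1) & set(m2) or sorted(m1 + m2) != list(range(sigma.shape[0])):
        raise ValueError("m1, m2 must bipartition the whole system")
    whole = _temporal_term(sigma, cross)
    parts = 0.0
    k_candidates = []
    for part in (m1, m2):
        s_m = sigma[np.ix_(part, part)]
        c_m = cross[np.ix_(part, part)]
        parts += _temporal_term(s_m, c_m)
        k_candidates.append(len(part) * LOG_2PIE + _logdet(s_m))
    return whole - parts, 0.5 * min(k_candidates)


def ei_empirical(
    model: GenerativeModel, m1: Sequence[int], m2: Sequence[int], tau: int = 1
) -> tuple[float, float]:
    """EI at lag tau across the whole-system bipartition {m1, m2}; returns (EI, K)."""
    sigma = stationary_cov(model)
    cross = lagged_cross_cov(model, tau, sigma)
    return _ei_from_covs(sigma, cross, m1, m2)


def _scan_bipartitions(sigma: np.ndarray, cross: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-mask temporal term and marginal log-determinant, batched by part size."""
    n = sigma.shape[0]
    masks, bits, sizes, comp_pos, groups = mask_tables(n)
    term = np.empty(len(masks))
    ld_sig = np.empty(len(masks))
    for sel, pidx, _ in groups:
        s_sub = gather_submatrices(sigma[None, :, :].repeat(len(sel), axis=0), np.arange(len(sel)), pidx)
        c_sub = gather_submatrices(cross[None, :, :].repeat(len(sel), axis=0), np.arange(len(sel)), pidx)
        sol = np.linalg.solve(s_sub, np.swapaxes(c_sub, 1, 2))
        cond = s_sub - c_sub @ sol
        ld_s = np.linalg.slogdet(s_sub)[1]
        ld_c = np.linalg.slogdet(cond)[1]
        term[sel] = 0.5 * (ld_s - ld_c)
        ld_sig[sel] = ld_s
    return term, ld_sig


def _phi_from_covs(sigma: np.ndarray, cross: np.ndarray, tau: int) -> EmpiricalPhiResult:
    n = sigma.shape[0]
    masks, bits, sizes, comp_pos, _ = mask_tables(n)
    whole = _temporal_term(sigma, cross)
    term, ld_sig = _scan_bipartitions(sigma, cross)
    ei = whole - (term + term[comp_pos])
    k_norm = 0.5 * np.minimum(
        sizes * LOG_2PIE + ld_sig, sizes[comp_pos] * LOG_2PIE + ld_sig[comp_pos]
    )
    ei_norm = ei / k_norm
    cand = np.nonzero(bits[:, 0])[0]
    vals = ei_norm[cand]
    best_val = vals.min()
    ties = cand[np.isclose(vals, best_val, rtol=1e-12, atol=0.0)]
    best = min(ties, key=lambda b: tuple(np.nonzero(bits[b])[0]))
    part_a = tuple(np.nonzero(bits[best])[0].tolist())
    part_b = tuple(np.nonzero(~bits[best])[0].tolist())
    return EmpiricalPhiResult(
        tau=tau,
        mib=Bipartition(part_a=part_a, part_b=part_b),
        ei=float(ei[best]),
        k_norm=float(k_norm[best]),
        phi=float(ei[best]),
    )


def phi_empirical(model: GenerativeModel, tau: int = 1, cap: int = 16) -> EmpiricalPhiResult:
    """Phi Empirical at one lag: unnormalized EI at the whole-system MIB."""
    if model.n > cap:
        raise ComputeCapError(
            f"bipartition scan over n={model.n} nodes needs 2^{model.n} evaluations; cap is {cap}"
        )
    if model.n < 2:
        raise ValueError("system must have at least 2 nodes")
    sigma = stationary_cov(model)
    cross = lagged_cross_cov(model, tau, sigma)
    return _phi_from_covs(sigma, cross, tau)


def phi_empirical_profile(
    model: GenerativeModel, taus: Sequence[int] = (1, 2, 3, 4), cap: int = 16
) -> PhiEmpiricalProfile:
    """Phi Empirical at each lag in ``taus`` plus the sum over lags."""
    per_tau = {tau: phi_empirical(model, tau, cap) for tau in taus}
    return PhiEmpiricalProfile(per_tau=per_tau, phi_sum=float(sum(r.phi for r in per_tau.values())))


def simulate(model: GenerativeModel, steps: int, rng: np.random.Generator, burn_in: int = 500) -> np.ndarray:
    """Simulate the recursion; returns a (steps, n) array of stationary samples."""
    n = model.n
    chol = np.linalg.cholesky(model.noise_cov)
    x = np.zeros(n)
    out = np.empty((steps, n))
    a = model.a1
    noise = rng.standard_normal((burn_in + steps, n)) @ chol.T
    for t in range(burn_in + steps):
        x = x @ a + noise[t]
        if t >= burn_in:
            out[t - burn_in] = x
    return out


def estimate_covariances(series: np.ndarray, tau: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample stationary covariance and lag-tau cross-covariance of a time series."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean(axis=0)
    sigma = x.T @ x / (x.shape[0] - 1)
    past = x[:-tau]
    present = x[tau:]
    cross = past.T @ present / (past.shape[0] - 1)
    return sigma, cross


def phi_empirical_from_series(series: np.ndarray, tau: int = 1) -> EmpiricalPhiResult:
    """Phi Empirical estimated from an observed time series (sample covariances)."""
    sigma, cross = estimate_covariances(series, tau)
    return _phi_from_covs(sigma, cross, tau)
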