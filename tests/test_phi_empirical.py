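"""Lag-based Phi Empirical: covariances, EI and bipartition scan."""

import math

import numpy as np
import pytest

from sdnet.generators import gen_fixed_column
from sdnet.phi2003 import ComputeCapError
from sdnet.phi_empirical import (
    GenerativeModel,
    ei_empirical,
    estimate_covariances,
    lagged_cross_cov,
    phi_empirical,
    phi_empirical_from_series,
    phi_empirical_profile,
    simulate,
    stationary_cov,
)


def random_stable_model(rng, n, scale=0.3):
    a = rng.standard_normal((n, n)) * scale / math.sqrt(n)
    a /= max(1.0, np.abs(np.linalg.eigvals(a)).max() / 0.7)
    return GenerativeModel(a1=a)


class TestStationaryCov:
    def test_no_dynamics_returns_noise_cov(self):
        m = GenerativeModel(a1=np.zeros((3, 3)))
        assert np.allclose(stationary_cov(m), np.eye(3))

    def test_scalar_ar1_closed_form(self):
        for a in (0.2, 0.5, 0.8):
            m = GenerativeModel(a1=np.array([[a]]))
            assert stationary_cov(m)[0, 0] == pytest.approx(1 / (1 - a * a))

    def test_symmetric_positive_definite(self, rng):
        m = random_stable_model(rng, 5)
        s = stationary_cov(m)
        assert np.allclose(s, s.T)
        assert np.linalg.eigvalsh(s).min() > 0


class TestLaggedCrossCov:
    def test_zero_dynamics_zero_cross(self):
        m = GenerativeModel(a1=np.zeros((3, 3)))
        assert np.allclose(lagged_cross_cov(m, 1), 0.0)

    def test_scalar_ar1_autocovariance(self):
        a = 0.6
        m = GenerativeModel(a1=np.array([[a]]))
        for tau in (1, 2, 3, 5):
            assert lagged_cross_cov(m, tau)[0, 0] == pytest.approx(a**tau / (1 - a * a))

    def test_decays_for_stable_system(self, rng):
        m = random_stable_model(rng, 4)
        assert np.abs(lagged_cross_cov(m, 30)).max() < 1e-3

    def test_matches_sample_cross_covariance(self, rng):
        m = random_stable_model(rng, 3)
        series = simulate(m, 200_000, rng)
        sig_hat, cross_hat = estimate_covariances(series, 2)
        assert np.allclose(cross_hat, lagged_cross_cov(m, 2), atol=0.03)


class TestEiEmpirical:
    def test_memoryless_system_has_zero_ei(self):
        m = GenerativeModel(a1=np.zeros((4, 4)))
        ei, k = ei_empirical(m, [0, 1], [2, 3])
        assert ei == pytest.approx(0.0, abs=1e-12)
        assert k > 0

    def test_decoupled_halves_zero_across_cut(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.4
        a[2, 3] = a[3, 2] = 0.4
        ei, _ = ei_empirical(GenerativeModel(a1=a), [0, 1], [2, 3])
        assert ei == pytest.approx(0.0, abs=1e-9)

    def test_two_node_explicit_joint_covariance_oracle(self, rng):
        # assemble the 4x4 joint covariance of (past, present) explicitly and
        # recompute every determinant term from it
        w = 0.35
        m = GenerativeModel(a1=np.array([[0, w], [0, 0.2]]))
        tau = 1
        sig = stationary_cov(m)
        cross = lagged_cross_cov(m, tau)
        joint = np.block([[sig, cross], [cross.T, sig]])

        def cond_logdet(idx_past, idx_present):
            j = joint[np.ix_(idx_past + idx_present, idx_past + idx_present)]
            sign, ld_joint = np.linalg.slogdet(j)
            sub = joint[np.ix_(idx_present, idx_present)]
            return ld_joint - np.linalg.slogdet(sub)[1]

        ld = lambda mat: np.linalg.slogdet(mat)[1]
        whole = 0.5 * (ld(sig) - cond_logdet([0, 1], [2, 3]))
        part1 = 0.5 * (ld(sig[:1, :1]) - cond_logdet([0], [2]))
        part2 = 0.5 * (ld(sig[1:, 1:]) - cond_logdet([1], [3]))
        expected = whole - part1 - part2
        ei, _ = ei_empirical(m, [0], [1], tau)
        assert ei == pytest.approx(expected, rel=1e-9)


class TestPhiEmpirical:
    def test_decoupled_duplicates_zero_phi_at_all_lags(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.4
        a[2, 3] = a[3, 2] = 0.4
        prof = phi_empirical_profile(GenerativeModel(a1=a), (1, 2, 3, 4))
        for res in prof.per_tau.values():
            assert res.phi == pytest.approx(0.0, abs=1e-9)
        assert prof.phi_sum == pytest.approx(0.0, abs=1e-9)

    def test_three_node_matches_exhaustive_oracle(self, rng):
        w = gen_fixed_column(3, 0.5, rng).weights
        m = GenerativeModel(a1=w)
        best = None
        for part_a in ([0], [1], [2], [0, 1], [0, 2], [1, 2]):
            part_b = [x for x in range(3) if x not in part_a]
            if 0 not in part_a:
                continue
            ei, k = ei_empirical(m, part_a, part_b, tau=1)
            if best is None or ei / k < best[0]:
                best = (ei / k, ei)
        res = phi_empirical(m, tau=1)
        assert res.phi == pytest.approx(best[1], rel=1e-9)

    def test_deterministic(self, rng):
        m = random_stable_model(rng, 5)
        r1, r2 = phi_empirical(m, 2), phi_empirical(m, 2)
        assert r1.phi == r2.phi and r1.mib == r2.mib

    def test_nonnegative_on_random_systems(self, rng):
        for _ in range(10):
            m = random_stable_model(rng, 5)
            assert phi_empirical(m, 1).phi >= -1e-9

    def test_cap_refusal(self):
        with pytest.raises(ComputeCapError):
            phi_empirical(GenerativeModel(a1=np.zeros((17, 17))), cap=16)


def test_analytic_matches_simulation_estimates(rng):
    """Phi from closed-form covariances agrees with Phi estimated from
    simulated time series, within three Monte-Carlo standard errors."""
    n_sys, reps, steps = 20, 5, 20_000
    for s in range(n_sys):
        srng = np.random.default_rng(9000 + s)
        m = random_stable_model(srng, 5)
        analytic = phi_empirical(m, tau=1).phi
        estimates = [
            phi_empirical_from_series(simulate(m, steps, np.random.default_rng(77 * s + r)), tau=1).phi
            for r in range(reps)
        ]
        se = np.std(estimates, ddof=1) / math.sqrt(reps)
        assert abs(analytic - np.mean(estimates)) < 3 * se + 5e-3
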