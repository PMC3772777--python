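"""2003 Phi: covariances, entropies, EI, MIB and subset search."""

import itertools
import math

import numpy as np
import pytest

from sdnet.generators import gen_fixed_column, normalize
from sdnet.phi2003 import (
    ComputeCapError,
    LOG_2PIE,
    LinearGaussianSystem,
    _bipartition_scan_generic,
    _bipartition_scan_reference,
    effective_information,
    gaussian_entropy,
    minimum_information_bipartition,
    mutual_information,
    stationary_covariance,
    system_phi,
)


def fixed_column_system(n, seed, **kw):
    rng = np.random.default_rng(seed)
    return LinearGaussianSystem(con=gen_fixed_column(n, 0.5, rng).weights, **kw)


class TestStationaryCovariance:
    def test_no_coupling_gives_noise_variances(self):
        cov = stationary_covariance(np.zeros((3, 3)), [1.0, 2.0, 3.0])
        assert np.allclose(cov, np.diag([1.0, 4.0, 9.0]))

    def test_symmetric_positive_definite(self, rng):
        con = gen_fixed_column(6, 0.5, rng).weights
        for mode in ("reference", "corrected"):
            cov = stationary_covariance(con, np.ones(6), mode)
            assert np.allclose(cov, cov.T)
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_reference_matches_hand_closed_form_two_nodes(self):
        # single edge 1->2 of weight w: the simultaneous-equation form gives
        # var1 = c1^2, cov12 = c1^2 w, var2 = c1^2 w^2 + c2^2
        for w in (0.1, 0.25, 0.45):
            cov = stationary_covariance(np.array([[0, w], [0, 0]]), [1.0, 0.5])
            assert np.allclose(cov, [[1.0, w], [w, w * w + 0.25]])

    def test_corrected_matches_long_run_simulation(self):
        # the Lyapunov solution is the covariance the recursion actually reaches
        rng = np.random.default_rng(3)
        con = gen_fixed_column(4, 0.5, rng).weights
        noise = np.array([1.0, 0.7, 1.3, 1.0])
        cov = stationary_covariance(con, noise, "corrected")
        x = np.zeros(4)
        samples = np.empty((200_000, 4))
        eps = rng.standard_normal((200_200, 4)) * noise
        for t in range(200_200):
            x = x @ con + eps[t]
            if t >= 200:
                samples[t - 200] = x
        emp = np.cov(samples.T)
        assert np.allclose(emp, cov, atol=3 * np.abs(cov).max() / math.sqrt(200))

    def test_reference_differs_from_temporal_truth(self):
        # the historical shortcut predicts instantaneous correlation across a
        # single edge, which the true lagged dynamics do not produce
        con = np.array([[0, 0.4], [0, 0]])
        ref = stationary_covariance(con, [1.0, 1.0], "reference")
        cor = stationary_covariance(con, [1.0, 1.0], "corrected")
        assert ref[0, 1] == pytest.approx(0.4)
        assert cor[0, 1] == pytest.approx(0.0)


class TestGaussianEntropy:
    def test_unit_variance_scalar(self):
        assert gaussian_entropy(np.array([[1.0]])) == pytest.approx(0.5 * LOG_2PIE)

    def test_identity_additivity(self):
        assert gaussian_entropy(np.eye(5)) == pytest.approx(2.5 * LOG_2PIE)

    def test_variance_scaling(self):
        s2 = 0.3
        assert gaussian_entropy(np.array([[s2]])) == pytest.approx(0.5 * LOG_2PIE + 0.5 * math.log(s2))

    def test_rejects_indefinite(self):
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            gaussian_entropy(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestMutualInformation:
    def test_independent_blocks(self):
        cov = np.diag([1.0, 2.0, 3.0, 4.0])
        assert mutual_information(cov, [0, 1], [2, 3]) == pytest.approx(0.0)

    def test_symmetry(self, rng):
        a = rng.standard_normal((4, 4))
        cov = a @ a.T + 4 * np.eye(4)
        assert mutual_information(cov, [0, 1], [2, 3]) == pytest.approx(
            mutual_information(cov, [2, 3], [0, 1])
        )

    def test_bivariate_closed_form(self):
        rho = 0.6
        cov = np.array([[1.0, rho], [rho, 1.0]])
        assert mutual_information(cov, [0], [1]) == pytest.approx(-0.5 * math.log(1 - rho * rho))


class TestEffectiveInformation:
    def test_decoupled_parts_share_nothing(self):
        con = np.zeros((4, 4))
        con[0, 1] = con[1, 0] = 0.3  # module {0,1}
        con[2, 3] = con[3, 2] = 0.3  # module {2,3}
        sys = LinearGaussianSystem(con=con)
        assert abs(effective_information(sys, [0, 1], [2, 3])) < 1e-9

    def test_directionality_follows_the_edge(self):
        sys = LinearGaussianSystem(con=np.array([[0, 0.4], [0, 0]]))
        fwd = effective_information(sys, [0], [1])
        back = effective_information(sys, [1], [0])
        assert fwd > 100 * max(back, 1e-12)

    def test_two_node_symbolic_closed_form(self):
        # perturbing the source makes MI = 0.5*ln(1 + cp^2 w^2 / ci^2)
        cp, ci = 1.0, 1e-5
        for w in np.arange(0.1, 0.5, 0.05):
            sys = LinearGaussianSystem(con=np.array([[0, w], [0, 0]]), c_p=cp, c_i=ci)
            expected = 0.5 * math.log(1 + cp**2 * w**2 / ci**2)
            # the covariance condition number is ~(cp/ci)^2 = 1e10, so ~1e-6
            # relative agreement is the attainable floating-point precision
            assert effective_information(sys, [0], [1]) == pytest.approx(expected, rel=1e-5)

    def test_bidirectional_ei_is_sum_of_directions(self, rng):
        sys = fixed_column_system(5, 17)
        a, b = [0, 2], [1, 3, 4]
        res = minimum_information_bipartition(sys, [0, 1, 2, 3, 4])
        # scan EI for this cut equals the two scalar directional calls
        from sdnet._masks import mask_tables

        masks, bits, _, comp_pos, _ = mask_tables(5)
        _, ei, _ = _bipartition_scan_reference(sys.con, sys.c_p, sys.c_i)
        mask_idx = (1 + 4) - 1  # bitmask 0b00101 -> positions {0, 2}
        expected = effective_information(sys, a, b) + effective_information(sys, b, a)
        assert ei[mask_idx] == pytest.approx(expected, rel=1e-6)


class TestMinimumInformationBipartition:
    def test_two_node_subset_has_single_cut(self):
        sys = fixed_column_system(6, 3)
        res = minimum_information_bipartition(sys, [1, 4])
        assert res.mib.part_a == (1,) and res.mib.part_b == (4,)
        assert res.phi == res.ei_unnormalized

    def test_decoupled_modules_cut_has_zero_phi(self):
        con = np.zeros((4, 4))
        con[0, 1] = con[1, 0] = 0.4
        con[2, 3] = con[3, 2] = 0.4
        res = minimum_information_bipartition(LinearGaussianSystem(con=con))
        assert set(res.mib.part_a) in ({0, 1}, {2, 3})
        assert abs(res.phi) < 1e-9

    def test_matches_exhaustive_scalar_oracle(self):
        sys = fixed_column_system(4, 29)
        subset = (0, 1, 2, 3)
        best = None
        for r in range(1, 3):
            for part_a in itertools.combinations(subset, r):
                part_b = tuple(x for x in subset if x not in part_a)
                if 0 not in part_a:
                    continue
                ei = effective_information(sys, part_a, part_b) + effective_information(
                    sys, part_b, part_a
                )
                norm = min(len(part_a), len(part_b)) * 0.5 * LOG_2PIE
                if best is None or ei / norm < best[0]:
                    best = (ei / norm, part_a, ei)
        res = minimum_information_bipartition(sys, subset)
        assert res.ei_normalized == pytest.approx(best[0], rel=1e-6)
        assert res.phi == pytest.approx(best[2], rel=1e-6)

    def test_vectorized_scan_agrees_with_generic_loop(self, rng):
        for _ in range(5):
            con = gen_fixed_column(5, 0.5, rng).weights
            mi_fast, ei_fast, _ = _bipartition_scan_reference(con, 1.0, 1e-5)
            mi_slow, ei_slow, _ = _bipartition_scan_generic(con, 1.0, 1e-5, "reference")
            assert np.allclose(mi_fast, mi_slow, rtol=1e-5)
            assert np.allclose(ei_fast, ei_slow, rtol=1e-5)


class TestSystemPhi:
    def test_three_node_scan_matches_per_subset_calls(self):
        sys = fixed_column_system(3, 7)
        subsets = [(0, 1), (0, 2), (1, 2), (0, 1, 2)]
        manual = max(minimum_information_bipartition(sys, s).phi for s in subsets)
        assert system_phi(sys).phi == pytest.approx(manual)

    def test_decoupled_duplicate_modules_whole_system_loses(self):
        con = np.zeros((4, 4))
        con[0, 1] = con[1, 0] = 0.4
        con[2, 3] = con[3, 2] = 0.4
        res = system_phi(LinearGaussianSystem(con=con))
        assert set(res.subset) in ({0, 1}, {2, 3})
        assert res.phi > 1.0  # within-module integration is substantial

    def test_invariant_under_relabeling(self, rng):
        con = gen_fixed_column(5, 0.5, rng).weights
        perm = rng.permutation(5)
        con_p = con[np.ix_(perm, perm)]
        phi1 = system_phi(LinearGaussianSystem(con=con)).phi
        phi2 = system_phi(LinearGaussianSystem(con=con_p)).phi
        assert phi1 == pytest.approx(phi2, rel=1e-9)

    def test_phi_nonnegative_and_reproducible(self, rng):
        for seed in range(8):
            sys = fixed_column_system(6, 100 + seed)
            r1 = system_phi(sys)
            r2 = system_phi(sys)
            assert r1.phi >= -1e-9
            assert r1.phi == r2.phi and r1.subset == r2.subset

    def test_cap_refusal_names_cost(self):
        sys = LinearGaussianSystem(con=np.zeros((13, 13)))
        with pytest.raises(ComputeCapError, match="cap"):
            system_phi(sys)


def test_spectral_radius_validation():
    with pytest.raises(ValueError, match="spectral radius"):
        LinearGaussianSystem(con=np.array([[0, 1.2], [1.2, 0]]))
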