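import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from prstuning.auc import (HeritabilityParams, compute_auc, compute_tau_sq,
                           empirical_auc, predicted_auc, sigma2_from_h2,
                           unadjusted_auc, youden_sensitivity)
from prstuning.ld import LDMatrix

from conftest import make_stats


class TestTauSq:
    def test_hand_expansion_two_snps(self):
        R = LDMatrix.from_dense(np.array([[1.0, 0.3], [0.3, 1.0]]))
        t0, t1 = compute_tau_sq(np.ones(2), np.ones(2), np.ones(2), R)
        assert t0 == pytest.approx(2 + 2 * 0.3)
        assert t1 == pytest.approx(2 + 2 * 0.3)

    def test_identity_reduces_to_weighted_sum(self, rng):
        omega = rng.standard_normal(10)
        s0 = rng.uniform(0.1, 0.5, 10)
        s1 = rng.uniform(0.1, 0.5, 10)
        t0, t1 = compute_tau_sq(omega, s0, s1, None)
        assert t0 == pytest.approx(np.sum(omega ** 2 * s0))
        assert t1 == pytest.approx(np.sum(omega ** 2 * s1))

    def test_blockwise_matches_dense_oracle(self, rng):
        # 30 SNPs in three blocks vs the dense quadratic form
        idx = [np.arange(0, 12), np.arange(12, 20), np.arange(20, 30)]
        blocks = []
        for ix in idx:
            A = rng.standard_normal((ix.size, ix.size))
            C = A @ A.T + ix.size * np.eye(ix.size)
            d = np.sqrt(np.diag(C))
            blocks.append((ix, C / np.outer(d, d)))
        R = LDMatrix(blocks, 30)
        omega = rng.standard_normal(30)
        s0 = rng.uniform(0.1, 0.6, 30)
        s1 = rng.uniform(0.1, 0.6, 30)
        t0, t1 = compute_tau_sq(omega, s0, s1, R)
        Rd = R.to_dense()
        v0, v1 = omega * np.sqrt(s0), omega * np.sqrt(s1)
        assert abs(t0 - v0 @ Rd @ v0) < 1e-12
        assert abs(t1 - v1 @ Rd @ v1) < 1e-12


class TestComputeAUC:
    def test_null_effects_give_half(self):
        est = compute_auc(np.ones(3), np.zeros(3), 1.0, 1.0)
        assert est.auc_point == pytest.approx(0.5)

    def test_single_snp_hand_value(self):
        est = compute_auc(np.array([1.0]), np.array([0.1]), 0.5, 0.5)
        assert est.delta_stat == pytest.approx(0.2)
        assert est.auc_point == pytest.approx(norm.cdf(0.2))

    def test_scale_invariance(self, rng):
        omega = rng.standard_normal(5)
        delta = rng.standard_normal(5) * 0.01
        a = compute_auc(omega, delta, 0.3, 0.4).auc_point
        b = compute_auc(3.7 * omega, delta, 0.3 * 3.7 ** 2, 0.4 * 3.7 ** 2).auc_point
        assert a == pytest.approx(b)

    def test_sign_symmetry(self, rng):
        omega = rng.standard_normal(5)
        delta = rng.standard_normal(5) * 0.01
        a = compute_auc(omega, delta, 0.3, 0.4).auc_point
        b = compute_auc(-omega, delta, 0.3, 0.4).auc_point
        assert a + b == pytest.approx(1.0)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_auc(np.ones(2), np.ones(2), 0.0, 0.0)


class TestPredictedAUC:
    def test_identical_draws_degenerate_ci(self):
        draws = np.tile([0.01, -0.02], (50, 1))
        est = predicted_auc(np.ones(2), draws, np.ones(2) * 0.5, np.ones(2) * 0.5)
        assert est.ci[0] == pytest.approx(est.ci[1])
        assert est.ci[0] == pytest.approx(est.auc_point)

    def test_zero_draws_give_half(self):
        est = predicted_auc(np.ones(3), np.zeros((20, 3)),
                            np.ones(3), np.ones(3))
        assert est.auc_point == pytest.approx(0.5)

    def test_point_is_mean_of_draw_aucs(self, rng):
        draws = rng.normal(0, 0.01, size=(200, 4))
        omega = rng.standard_normal(4)
        s = rng.uniform(0.2, 0.5, 4)
        est = predicted_auc(omega, draws, s, s)
        t0, t1 = compute_tau_sq(omega, s, s, None)
        expect = norm.cdf(2 * draws @ omega / np.sqrt(t0 + t1)).mean()
        assert est.auc_point == pytest.approx(expect, abs=1e-12)


class TestUnadjustedAUC:
    def test_null_z_gives_half(self):
        stats = make_stats(np.zeros(4))
        est = unadjusted_auc(stats, np.ones(4))
        assert est.auc_point == pytest.approx(0.5)

    def test_equals_plugin_delta(self, small_stats):
        omega = np.linspace(-1, 1, small_stats.n_snps)
        s0, s1 = small_stats.group_variances()
        t0, t1 = compute_tau_sq(omega, s0, s1, None)
        direct = compute_auc(omega, small_stats.z * small_stats.s, t0, t1)
        est = unadjusted_auc(small_stats, omega)
        assert est.auc_point == pytest.approx(direct.auc_point, abs=1e-15)


def _brute_force_auc(cases, controls):
    """Pairwise-comparison oracle (exact, ties half)."""
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


class TestEmpiricalAUC:
    def test_perfect_separation(self):
        assert empirical_auc([2, 3], [0, 1]) == 1.0

    def test_single_tie_is_half(self):
        assert empirical_auc([1.0], [1.0]) == 0.5

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=25),
           st.lists(st.integers(-5, 5), min_size=1, max_size=25))
    def test_matches_brute_force_oracle(self, cases, controls):
        got = empirical_auc(np.array(cases, float), np.array(controls, float))
        assert got == pytest.approx(_brute_force_auc(cases, controls), abs=1e-12)

    def test_matches_binormal_closed_form(self, rng):
        eta0, eta1, tau = 0.0, 0.8, 1.0
        n = 200
        cases = rng.normal(eta1, tau, n)
        controls = rng.normal(eta0, tau, n)
        expect = norm.cdf((eta1 - eta0) / np.sqrt(2 * tau ** 2))
        se = np.sqrt(expect * (1 - expect) * (1 / n + 1 / n))  # conservative
        assert abs(empirical_auc(cases, controls) - expect) < 3 * se

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1.0])


class TestYouden:
    def test_perfect_separation(self):
        cut, sens, spec = youden_sensitivity([5, 6, 7], [1, 2, 3])
        assert sens == 1.0 and spec == 1.0

    def test_identical_groups_smallest_cutoff(self):
        cut, sens, spec = youden_sensitivity([1, 2, 3], [1, 2, 3])
        assert cut == 1.0
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_equal_variance_normals_cutoff_near_midpoint(self, rng):
        eta0, eta1, tau = 0.0, 1.0, 0.5
        cases = rng.normal(eta1, tau, 20_000)
        controls = rng.normal(eta0, tau, 20_000)
        cut, _, _ = youden_sensitivity(cases, controls)
        assert abs(cut - 0.5) < 0.05 * tau


class TestHeritabilityConversion:
    def test_hand_value_at_half_prevalence(self):
        h = HeritabilityParams(h2_liability=0.3, kappa=0.5, M=1000, pi=0.05,
                               n0=2000, n1=2000)
        factor = norm.pdf(0.0) ** 2 / 0.5 ** 2 / 0.5 ** 2
        expect = h.n_eff * 0.3 / (4 * 1000 * 0.05) * factor
        assert sigma2_from_h2(h) == pytest.approx(expect, rel=1e-12)
        assert factor == pytest.approx(2.546479, rel=1e-6)

    def test_zero_heritability(self):
        h = HeritabilityParams(0.0, 0.1, 100, 0.1, 100, 100)
        assert sigma2_from_h2(h) == 0.0

    def test_doubling_m_halves_sigma2(self):
        a = sigma2_from_h2(HeritabilityParams(0.3, 0.01, 1000, 0.05, 500, 500))
        b = sigma2_from_h2(HeritabilityParams(0.3, 0.01, 2000, 0.05, 500, 500))
        assert a == pytest.approx(2 * b, rel=1e-12)

    def test_no_risk_snps_rejected(self):
        with pytest.raises(ValueError):
            sigma2_from_h2(HeritabilityParams(0.3, 0.01, 1000, 0.0, 500, 500))
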