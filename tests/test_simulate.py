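import numpy as np
import pytest
from scipy.stats import norm

from prstuning.auc import compute_tau_sq, empirical_auc
from prstuning.simulate import (SimConfig, ar1_ld_matrix,
                                effective_adjacent_rho, markov_corr_matrix,
                                preset, simulate_ar1_haplotypes,
                                simulate_study)


class TestAr1Matrix:
    def test_rho_zero_is_identity(self):
        np.testing.assert_array_equal(ar1_ld_matrix(5, 0.0), np.eye(5))

    def test_lag_five_value(self):
        R = ar1_ld_matrix(10, 0.2)
        assert R[0, 5] == pytest.approx(3.2e-4)

    def test_always_psd(self):
        R = ar1_ld_matrix(100, 0.9)
        assert np.linalg.eigvalsh(R)[0] > 0

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            ar1_ld_matrix(5, 1.0)


class TestHaplotypes:
    def test_independent_columns_at_rho_zero(self):
        rng = np.random.default_rng(0)
        f = np.full(30, 0.4)
        H = simulate_ar1_haplotypes(20_000, f, 0.0, rng)
        freqs = H.mean(axis=0)
        se = np.sqrt(0.4 * 0.6 / 20_000)
        assert np.all(np.abs(freqs - 0.4) < 4 * se)
        r = np.corrcoef(H[:, :2].T)[0, 1]
        assert abs(r) < 0.03

    def test_lag_correlations_decay_as_powers(self):
        rng = np.random.default_rng(1)
        f = np.full(40, 0.5)
        H = simulate_ar1_haplotypes(50_000, f, 0.2, rng).astype(float)
        C = np.corrcoef(H.T)
        assert abs(np.diag(C, 1).mean() - 0.2) < 0.01
        assert abs(np.diag(C, 2).mean() - 0.04) < 0.01

    def test_single_row_valid(self):
        H = simulate_ar1_haplotypes(1, np.full(10, 0.5), 0.2,
                                    np.random.default_rng(2))
        assert H.shape == (1, 10)
        assert set(np.unique(H)) <= {0, 1}

    def test_infeasible_pair_named_without_clip(self):
        f = np.array([0.05, 0.95])
        with pytest.raises(ValueError, match="SNPs 0 and 1"):
            simulate_ar1_haplotypes(10, f, 0.5, np.random.default_rng(3))

    def test_clip_to_feasible_accepts(self):
        f = np.array([0.05, 0.95, 0.5])
        H = simulate_ar1_haplotypes(100, f, 0.5, np.random.default_rng(3),
                                    clip_to_feasible=True)
        assert H.shape == (100, 3)


class TestMarkovCorr:
    def test_matches_pairwise_products(self, rng):
        rhos = rng.uniform(0.05, 0.3, 6)
        R = markov_corr_matrix(rhos)
        for i in range(7):
            for j in range(i + 1, 7):
                assert R[i, j] == pytest.approx(np.prod(rhos[i:j]), rel=1e-12)

    def test_feasible_bound_formula(self):
        f = np.array([0.1, 0.9])
        odds = (0.1 / 0.9) / (0.9 / 0.1)
        assert effective_adjacent_rho(f, 0.9)[0] == pytest.approx(
            0.999 * np.sqrt(odds))


class TestSimulateStudy:
    def test_null_z_standard_normal(self):
        cfg = SimConfig(M=10_000, n0=2_000, n1=2_000, pi_true=0.0,
                        n_test_cases=10, n_test_controls=10, n_ref=0, seed=0)
        study = simulate_study(cfg)
        # 3 standard errors of the mean and variance of 10,000 N(0,1) draws
        assert abs(study.stats.z.mean()) < 3 / np.sqrt(10_000)
        assert abs(study.stats.z.var() - 1.0) < 3 * np.sqrt(2 / 10_000)

    def test_signal_presence_at_study_conditions(self):
        cfg = preset("study_independent", n=10_000, seed=1,
                     n_test_cases=10, n_test_controls=10, n_ref=0)
        study = simulate_study(cfg)
        assert np.mean(np.abs(study.stats.z) > 1.96) > 0.07

    def test_observed_difference_tracks_truth(self):
        cfg = SimConfig(M=2_000, n0=5_000, n1=5_000, seed=2,
                        n_test_cases=10, n_test_controls=10, n_ref=0)
        study = simulate_study(cfg)
        diff = study.stats.f1_hat - study.stats.f0_hat
        t = study.truth
        se = np.sqrt(t.f0 * (1 - t.f0) / (2 * cfg.n0)
                     + t.f1 * (1 - t.f1) / (2 * cfg.n1))
        assert np.mean(np.abs(diff - t.delta_true) < 3 * se) > 0.99

    def test_independent_delta_equals_beta(self):
        cfg = SimConfig(M=500, seed=3, n_test_cases=10, n_test_controls=10,
                        n_ref=0)
        t = simulate_study(cfg).truth
        clipped = (t.f1 <= 0.01) | (t.f1 >= 0.99)
        np.testing.assert_array_equal(t.delta_true[~clipped],
                                      t.beta_true[~clipped])

    def test_bit_reproducible_under_seed(self):
        cfg = preset("study_ar1", n=2_000, M=200, seed=4,
                     n_test_cases=20, n_test_controls=20, n_ref=20)
        a, b = simulate_study(cfg), simulate_study(cfg)
        np.testing.assert_array_equal(a.stats.z, b.stats.z)
        np.testing.assert_array_equal(a.test_cases, b.test_cases)
        np.testing.assert_array_equal(a.panel.genotypes, b.panel.genotypes)

    def test_oracle_weights_auc_matches_closed_form(self):
        # testing-cohort AUC of the true-delta weight set agrees with
        # Phi(Delta) computed from the generating group frequencies
        cfg = SimConfig(M=2_000, n0=5_000, n1=5_000, seed=5, n_ref=0,
                        n_test_cases=1_000, n_test_controls=1_000)
        study = simulate_study(cfg)
        t = study.truth
        omega = t.delta_true
        s0_sq, s1_sq = 2 * t.f0 * (1 - t.f0), 2 * t.f1 * (1 - t.f1)
        t0, t1 = compute_tau_sq(omega, s0_sq, s1_sq, None)
        expect = norm.cdf(2 * omega @ t.delta_true / np.sqrt(t0 + t1))
        got = empirical_auc(study.test_cases @ omega,
                            study.test_controls @ omega)
        se = np.sqrt(expect * (1 - expect) * (2 / 1000.0))
        assert abs(got - expect) < 3 * se

    def test_heterogeneity_presets_run(self):
        for name in ("study_het_freq", "study_het_effect", "study_het_ld"):
            cfg = preset(name, n=1_000, M=100, seed=6, n_test_cases=20,
                         n_test_controls=20, n_ref=20)
            study = simulate_study(cfg)
            assert study.stats.n_snps == 100

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(ld="banana")
        with pytest.raises(ValueError):
            SimConfig(rho=1.5, ld="ar1")
        with pytest.raises(ValueError):
            preset("nope")
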