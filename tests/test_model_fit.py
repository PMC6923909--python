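"""Mixed-model fitting: closed-form nested ANOVA, REML profile, and their agreement."""

import numpy as np
import pytest

from fmtlmm import (
    ExperimentDesign,
    average_log_expression,
    fit_balanced_anova,
    fit_lmm,
    fit_reml_profile,
)
from fmtlmm.model_fit import _reml_neg_loglik

from conftest import simulate_null_gene_matrix


def brute_force_contrast_variance(design, sigma_r2, sigma_e2):
    """Var(Lβ̂) from the full V = ZGZ' + R via GLS algebra."""
    X = design.fixed_effects_matrix()
    Z = design.random_effects_matrix()
    V = sigma_r2 * Z @ Z.T + sigma_e2 * np.eye(design.n_samples)
    C = np.linalg.inv(X.T @ np.linalg.solve(V, X))
    L = design.contrast
    return float(L @ C @ L)


class TestAverageLogExpression:
    def test_constant_row(self):
        assert average_log_expression(np.full((1, 7), 7.0))[0] == 7.0

    def test_arithmetic_mean(self):
        assert average_log_expression(np.array([[1.0, 2, 3, 4]]))[0] == 2.5

    def test_permutation_invariant(self, rng):
        Y = rng.normal(size=(5, 8))
        perm = rng.permutation(8)
        np.testing.assert_allclose(
            average_log_expression(Y), average_log_expression(Y[:, perm])
        )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            average_log_expression(np.empty((0, 0)))


class TestBalancedAnova:
    def test_hand_decomposition(self, tiny_dataset):
        Y, design = tiny_dataset
        f = fit_balanced_anova(Y, design)
        assert f.beta_hat[0] == pytest.approx(-4.0)
        assert f.s2_e[0] == pytest.approx(2.0)
        assert f.d_e[0] == 4
        assert f.s2_r[0] == 0.0  # MS_B=1 < MS_W=2, truncated
        assert f.s2_r_raw[0] == pytest.approx(-0.5)
        assert f.d_r[0] == 2

    def test_degenerate_constant_data(self, design_3x2):
        f = fit_balanced_anova(np.full((1, 12), 3.0), design_3x2)
        assert f.beta_hat[0] == 0.0
        assert f.s2_e[0] == 0.0
        assert f.s2_r[0] == 0.0

    def test_variance_coefficients(self, design_3x2):
        f = fit_balanced_anova(np.zeros((1, 12)), design_3x2)
        assert f.a_r[0] == pytest.approx(2 / 3)
        assert f.a_e[0] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n_s,n_r", [(2, 2), (3, 2), (4, 3)])
    def test_coefficients_match_brute_force_gls(self, n_s, n_r):
        design = ExperimentDesign.balanced_two_group(n_s, n_r)
        f = fit_balanced_anova(np.zeros((1, design.n_samples)), design)
        for sr2, se2 in [(0.5, 0.3), (0.0, 1.0), (2.0, 0.1)]:
            expected = brute_force_contrast_variance(design, sr2, se2)
            assert f.a_r[0] * sr2 + f.a_e[0] * se2 == pytest.approx(expected, rel=1e-10)

    def test_shift_invariance_and_group_swap(self, rng, design_3x2):
        Y = rng.normal(size=(4, 12))
        f = fit_balanced_anova(Y, design_3x2)
        shifted = fit_balanced_anova(Y + 11.5, design_3x2)
        np.testing.assert_allclose(shifted.beta_hat, f.beta_hat, atol=1e-12)
        swapped_design = ExperimentDesign(
            sample_ids=design_3x2.sample_ids,
            group=np.where(design_3x2.group == "g1", "g2", "g1"),
            subject=design_3x2.subject,
        )
        swapped = fit_balanced_anova(Y, swapped_design)
        np.testing.assert_allclose(swapped.beta_hat, -f.beta_hat, atol=1e-12)

    def test_single_technical_replicate_rejected(self):
        design = ExperimentDesign.balanced_two_group(3, 1)
        with pytest.raises(ValueError, match="not separable"):
            fit_balanced_anova(np.zeros((1, 6)), design)

    def test_missing_values_rejected(self, design_3x2):
        Y = np.zeros((1, 12))
        Y[0, 3] = np.nan
        with pytest.raises(ValueError, match="missing|finite"):
            fit_balanced_anova(Y, design_3x2)

    def test_estimators_unbiased_under_model(self, rng, design_3x2):
        """E[s_e²]=σ_e² and E[MS_B/n_r]=σ_r²+σ_e²/n_r (Monte Carlo, 10k genes)."""
        sigma_e, sigma_r = 0.3, 0.5
        Y = simulate_null_gene_matrix(rng, 10_000, design_3x2, sigma_e, sigma_r)
        f = fit_balanced_anova(Y, design_3x2)
        assert f.s2_e.mean() == pytest.approx(sigma_e, rel=0.03)
        ms_b_over_nr = f.s2_r_raw + f.s2_e / design_3x2.n_r
        assert ms_b_over_nr.mean() == pytest.approx(sigma_r + sigma_e / 2, rel=0.03)


class TestRemlProfile:
    def test_matches_anova_on_balanced_interior_data(self, rng):
        """On balanced data with clear between-subject spread, REML = ANOVA."""
        design = ExperimentDesign.balanced_two_group(3, 3)
        Z = design.random_effects_matrix()
        checked = 0
        for _ in range(8):
            y = (rng.normal(0, 1.2, design.n_subjects) @ Z.T
                 + rng.normal(0, 0.4, design.n_samples))
            anova = fit_balanced_anova(y[None, :], design)
            if anova.s2_r_raw[0] <= 1e-3:  # keep to interior optima
                continue
            reml = fit_reml_profile(y, design)
            assert reml.beta_hat[0] == pytest.approx(anova.beta_hat[0], abs=1e-8)
            assert reml.s2_e[0] == pytest.approx(anova.s2_e[0], abs=1e-8)
            assert reml.s2_r[0] == pytest.approx(anova.s2_r[0], abs=1e-8)
            assert reml.a_r[0] == pytest.approx(anova.a_r[0], abs=1e-8)
            assert reml.a_e[0] == pytest.approx(anova.a_e[0], abs=1e-8)
            checked += 1
        assert checked >= 3

    def test_zero_between_subject_spread_hits_boundary(self):
        design = ExperimentDesign.balanced_two_group(3, 2)
        # within-subject pairs differ, subject means all equal within group
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 2.0, 0.0, 2.0, 0.0, 2.0, 0.0])
        f = fit_reml_profile(y, design)
        assert f.s2_r[0] == 0.0

    def test_profile_grid_scan_oracle(self, rng):
        """Optimizer matches a brute-force scan over the log-ratio grid."""
        design = ExperimentDesign.balanced_two_group(3, 2)
        Z = design.random_effects_matrix()
        y = (rng.normal(0, 1.0, design.n_subjects) @ Z.T
             + rng.normal(0, 0.5, design.n_samples))
        X = design.fixed_effects_matrix()
        ZZt = Z @ Z.T
        grid = np.linspace(-12, 12, 20001)
        vals = [_reml_neg_loglik(g, y, X, ZZt, 12, 2) for g in grid]
        best = grid[int(np.argmin(vals))]
        f = fit_reml_profile(y, design)
        lam_opt = f.s2_r_raw[0] / f.s2_e[0]
        assert abs(min(vals) - _reml_neg_loglik(np.log(max(lam_opt, 1e-12)), y, X, ZZt, 12, 2)) < 1e-6
        assert np.log(max(lam_opt, np.exp(-12))) == pytest.approx(best, abs=5e-3)

    def test_unbalanced_design_fits(self, rng):
        """REML runs on an unbalanced layout and df follow containment."""
        design = ExperimentDesign(
            sample_ids=[f"s{i}" for i in range(9)],
            group=np.array(["a"] * 5 + ["b"] * 4),
            subject=np.array(["u1", "u1", "u2", "u2", "u2", "u3", "u3", "u4", "u4"]),
        )
        y = rng.normal(size=9)
        f = fit_reml_profile(y, design)
        assert f.d_r[0] == 4 - 2
        assert f.d_e[0] == 9 - 4
        assert f.s2_e[0] > 0
        assert f.a_r[0] > 0 and f.a_e[0] > 0

    def test_confounded_design_rejected(self, rng):
        design = ExperimentDesign(
            sample_ids=["a", "b", "c", "d"],
            group=np.array(["x", "x", "y", "y"]),
            subject=np.array(["s1", "s2", "s3", "s4"]),
        )
        with pytest.raises(ValueError, match="confounded"):
            fit_reml_profile(rng.normal(size=4), design)

    def test_euler_decomposition_matches_lcl(self, rng):
        """a_r σ̂_r² + a_e σ̂_e² reproduces LĈL' at the REML estimates."""
        design = ExperimentDesign(
            sample_ids=[f"s{i}" for i in range(10)],
            group=np.array(["a"] * 6 + ["b"] * 4),
            subject=np.array(["u1"] * 3 + ["u2"] * 3 + ["u3"] * 2 + ["u4"] * 2),
        )
        Z = design.random_effects_matrix()
        y = rng.normal(0, 1.0, design.n_subjects) @ Z.T + rng.normal(0, 0.5, 10)
        f = fit_reml_profile(y, design)
        direct = brute_force_contrast_variance(design, f.s2_r_raw[0], f.s2_e[0])
        assert f.a_r[0] * f.s2_r_raw[0] + f.a_e[0] * f.s2_e[0] == pytest.approx(direct, rel=1e-8)


def test_fit_lmm_dispatches(rng, design_3x2):
    Y = rng.normal(size=(3, 12))
    balanced = fit_lmm(Y, design_3x2)
    assert len(balanced) == 3
    unbal = ExperimentDesign(
        sample_ids=[f"s{i}" for i in range(9)],
        group=np.array(["a"] * 5 + ["b"] * 4),
        subject=np.array(["u1", "u1", "u2", "u2", "u2", "u3", "u3", "u4", "u4"]),
    )
    f = fit_lmm(rng.normal(size=(2, 9)), unbal)
    assert len(f) == 2
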