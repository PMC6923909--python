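"""Moderated t assembly, effective df, p-values and PFER control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fmtlmm import (
    ExperimentDesign,
    df_satterthwaite,
    df_vc,
    fit_balanced_anova,
    moderated_contrast_variance,
    moderated_t_test,
    pfer_adjust,
    t_test_pvalue,
)

from conftest import simulate_null_gene_matrix


class TestModeratedContrastVariance:
    def test_arithmetic(self):
        assert moderated_contrast_variance(2 / 3, 1 / 3, 0.6, 0.3) == pytest.approx(0.5)

    def test_zero_random_variance(self):
        assert moderated_contrast_variance(2 / 3, 1 / 3, 0.0, 0.9) == pytest.approx(0.3)

    def test_matrix_oracle_on_balanced_instance(self):
        """Equals L(X'Ṽ⁻¹X)⁻¹L' with Ṽ built from the moderated variances."""
        design = ExperimentDesign.balanced_two_group(3, 2)  # 12 samples
        st_r, st_e = 0.45, 0.21
        X = design.fixed_effects_matrix()
        Z = design.random_effects_matrix()
        V = st_r * Z @ Z.T + st_e * np.eye(12)
        L = design.contrast
        direct = float(L @ np.linalg.inv(X.T @ np.linalg.solve(V, X)) @ L)
        f = fit_balanced_anova(np.zeros((1, 12)), design)
        assert moderated_contrast_variance(f.a_r[0], f.a_e[0], st_r, st_e) == pytest.approx(
            direct, rel=1e-10
        )

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            moderated_contrast_variance(-0.1, 0.3, 1.0, 1.0)


class TestDfVc:
    def test_additive(self):
        assert df_vc(4.0, 6.0) == 10.0

    def test_unmoderated_limit(self):
        assert df_vc(4.0, 0.0) == 4.0

    def test_monotone_in_prior_df(self):
        assert df_vc(4.0, 2.0) < df_vc(4.0, 3.0) < df_vc(4.0, 10.0)


class TestSatterthwaite:
    def test_symmetric_case(self):
        assert df_satterthwaite([(1.0, 7.0), (1.0, 7.0)]) == pytest.approx(14.0)

    def test_single_component(self):
        assert df_satterthwaite([(1.3, 4.0), (0.0, 10.0)]) == pytest.approx(4.0)

    def test_direct_evaluation(self):
        # (1 + 0.5)² / (1/4 + 0.25/10) = 2.25/0.275
        assert df_satterthwaite([(1.0, 4.0), (0.5, 10.0)]) == pytest.approx(2.25 / 0.275)

    def test_matches_chi_square_mixture_simulation(self, rng):
        """ν_eff chosen so the scaled-χ² approximation matches the mixture's variance."""
        u1, v1, u2, v2 = 1.0, 4.0, 0.5, 10.0
        draws = u1 * rng.chisquare(v1, 200_000) / v1 + u2 * rng.chisquare(v2, 200_000) / v2
        # Var of the mixture = 2(u1²/v1 + u2²/v2); matching scaled-χ²_ν gives ν_eff
        nu_mc = 2 * draws.mean() ** 2 / draws.var()
        assert df_satterthwaite([(u1, v1), (u2, v2)]) == pytest.approx(nu_mc, rel=0.02)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            df_satterthwaite([(0.0, 4.0), (0.0, 10.0)])

    @settings(max_examples=100, deadline=None)
    @given(
        u1=st.floats(min_value=1e-6, max_value=1e3),
        u2=st.floats(min_value=1e-6, max_value=1e3),
        v1=st.floats(min_value=0.5, max_value=200),
        v2=st.floats(min_value=0.5, max_value=200),
    )
    def test_bounds(self, u1, u2, v1, v2):
        nu = df_satterthwaite([(u1, v1), (u2, v2)])
        assert min(v1, v2) - 1e-9 <= nu <= v1 + v2 + 1e-9


class TestTTestPvalue:
    def test_zero_effect(self):
        t, p = t_test_pvalue(0.0, 1.0, 10.0)
        assert t == 0.0 and p == 1.0

    def test_symmetry(self):
        _, p_pos = t_test_pvalue(1.7, 0.5, 8.0)
        _, p_neg = t_test_pvalue(-1.7, 0.5, 8.0)
        assert p_pos == p_neg

    def test_known_tail(self):
        t, p = t_test_pvalue(2.0, 1.0, 10.0)
        assert t == 2.0
        assert p == pytest.approx(0.073388, abs=5e-6)

    def test_huge_df_uses_normal(self):
        _, p = t_test_pvalue(2.0, 1.0, 1e7)
        assert p == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-12)

    def test_na_propagation(self):
        t, p = t_test_pvalue(np.array([1.0]), np.array([0.0]), np.array([5.0]))
        assert np.isnan(t[0]) and np.isnan(p[0])


class TestPferAdjust:
    def test_threshold_definition(self):
        p = np.full(12_000, 1.0)
        p[0] = 5 / 12_000
        p[1] = 5 / 12_000 + 1e-9
        rej = pfer_adjust(p, k=5)
        assert rej[0] and not rej[1]  # closed threshold: p ≤ k/m

    def test_all_ones_no_rejections(self):
        assert pfer_adjust(np.ones(100), k=5).sum() == 0

    def test_expected_false_positives_under_null(self, rng):
        """Uniform p-values: mean rejections over replicates ≈ k."""
        m, k, reps = 12_000, 5, 1000
        counts = [(rng.uniform(size=m) <= k / m).sum() for _ in range(reps)]
        # identical in law to pfer_adjust on uniform p; run through the function once
        assert pfer_adjust(rng.uniform(size=m), k).sum() < 30
        assert 4.5 <= np.mean(counts) <= 5.5

    def test_na_never_rejected(self):
        p = np.array([np.nan, 1e-9])
        rej = pfer_adjust(p, k=1.0)
        assert not rej[0] and rej[1]

    def test_monotone_in_k(self, rng):
        p = rng.uniform(size=5000)
        r1 = pfer_adjust(p, k=2)
        r2 = pfer_adjust(p, k=7)
        assert np.all(r2[r1])  # rejections at k=2 ⊆ rejections at k=7


class TestModeratedTTest:
    def test_ot_equals_fmt_with_zero_prior_df(self, rng, design_3x2):
        Y = simulate_null_gene_matrix(rng, 300, design_3x2)
        fits = fit_balanced_anova(Y, design_3x2)
        for flavor in ("VC", "Sat"):
            ot = moderated_t_test(fits, method=f"OT-{flavor}", k=5)
            fmt0 = moderated_t_test(fits, method=f"FMT-{flavor}", k=5,
                                    hyper_e=(0.0, 1.0), hyper_r=(0.0, 1.0))
            np.testing.assert_array_equal(
                ot.sort_values("gene_id")["p"].to_numpy(),
                fmt0.sort_values("gene_id")["p"].to_numpy(),
            )

    def test_oracle_prior_type_one_error_calibration(self, rng):
        """FMT-VC with the true hyperparameters is calibrated at the PFER threshold.

        Null genes whose variances follow the hierarchical model exactly; with
        the oracle (d0, s0²) supplied, per-gene type-I error at α=k/m should be
        within 3 binomial SEs of nominal.
        """
        from fmtlmm import fit_balanced_anova as fba

        design = ExperimentDesign.balanced_two_group(3, 2)
        G = 1_000_000
        alpha_level = 5 / 12_000
        d0_e, s0_e, d0_r, s0_r = 8.0, 0.06, 7.0, 0.18
        sigma2_e = d0_e * s0_e / rng.chisquare(d0_e, G)
        sigma2_r = d0_r * s0_r / rng.chisquare(d0_r, G)
        Z = design.random_effects_matrix()
        S = rng.standard_normal((G, design.n_subjects)) * np.sqrt(sigma2_r)[:, None]
        Y = S @ Z.T + rng.standard_normal((G, design.n_samples)) * np.sqrt(sigma2_e)[:, None]
        fits = fba(Y, design)
        res = moderated_t_test(fits, method="FMT-VC", k=alpha_level * G,
                               hyper_e=(d0_e, s0_e), hyper_r=(d0_r, s0_r))
        n_rej = int(res["rejected"].sum())
        expected = alpha_level * G
        se = np.sqrt(expected)
        assert abs(n_rej - expected) <= 3 * se, (n_rej, expected)

    def test_results_sorted_and_schema(self, rng, design_3x2):
        Y = simulate_null_gene_matrix(rng, 200, design_3x2)
        fits = fit_balanced_anova(Y, design_3x2)
        res = moderated_t_test(fits, method="FMT-Sat", k=5, with_fdr=True)
        assert list(res.columns) == ["gene_id", "alpha", "beta_hat", "t", "df_eff",
                                     "p", "rejected", "method_tag", "fdr"]
        p = res["p"].to_numpy()
        assert np.all(np.diff(p[np.isfinite(p)]) >= 0)
        assert (res["method_tag"] == "FMT-Sat").all()
        assert res["p"].dropna().between(0, 1).all()
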