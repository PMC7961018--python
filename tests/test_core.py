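"""Null model fitting and the burden / variance-component GxE score tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mixge import scenario, simulate_cohort
from mixge.core import (
    DesignMatrices,
    GxEConfig,
    build_design,
    burden_gxe_score_test,
    combine_fixed_and_vc,
    fit_null_model,
    mixge_gene_test,
    variance_component_gxe_test,
)


def _manual_design(n, m, seed, dummy_ref_first=True):
    """A DesignMatrices built by hand, allowing alternate dummy coding."""
    rng = np.random.default_rng(seed)
    sex = rng.integers(0, 2, n).astype(float)
    grp = rng.integers(0, 3, n)
    if dummy_ref_first:
        dummies = np.column_stack([(grp == 1).astype(float), (grp == 2).astype(float)])
    else:  # reference category 2 instead of 0
        dummies = np.column_stack([(grp == 0).astype(float), (grp == 1).astype(float)])
    X = np.column_stack([np.ones(n), sex, dummies])
    E = rng.normal(8.5, 4.5, n)
    G = rng.integers(0, 3, size=(n, m)).astype(float)
    y = 10 + 2 * sex + 0.5 * E + rng.normal(0, 3, n)
    return DesignMatrices(
        y=y,
        X=X,
        E=E,
        G=G,
        subject_ids=[str(i) for i in range(n)],
        x_names=["intercept", "sex", "d1", "d2"],
        snp_ids=[f"s{j}" for j in range(m)],
    ), (sex, grp, y, E, G)


# ---------------------------------------------------------------------------
# build_design


class TestBuildDesign:
    def test_two_ethnic_groups_one_dummy(self, small_cohort):
        cohort, gm, _ = small_cohort
        cohort = cohort.copy()
        cohort["ethnicity"] = np.where(
            np.arange(len(cohort)) % 2 == 0, "groupA", "groupB"
        )
        d = build_design(cohort, gm, "volume")
        assert sum(n.startswith("eth_") for n in d.x_names) == 1

    def test_postnatal_covariate_by_timepoint(self, small_cohort):
        cohort, gm, _ = small_cohort
        cohort = cohort.copy()
        cohort["E_postnatal"] = 6.0 + (np.arange(len(cohort)) % 5)
        d_birth = build_design(cohort, gm, "volume")
        assert "E_postnatal" not in d_birth.x_names
        cohort6 = cohort.assign(timepoint="6y")
        d_6y = build_design(cohort6, gm, "volume")
        assert "E_postnatal" in d_6y.x_names

    def test_unmatched_subjects_dropped(self, small_cohort):
        cohort, gm, _ = small_cohort
        extra = cohort.iloc[:1].assign(subject_id="NOT_GENOTYPED")
        d = build_design(pd.concat([cohort, extra]), gm, "volume")
        assert d.n == len(cohort)
        assert d.n_dropped == 1

    def test_insufficient_sample_raises(self, small_cohort):
        cohort, gm, _ = small_cohort
        with pytest.raises(ValueError, match="insufficient sample"):
            build_design(cohort.head(8), gm, "volume")


# ---------------------------------------------------------------------------
# null model


class TestNullModel:
    def test_no_snps_reduces_to_ols(self, small_cohort):
        cohort, gm, _ = small_cohort
        d = build_design(cohort, gm.select_snps([]), "volume")
        fit = fit_null_model(d)
        U = np.column_stack([d.X, d.E])
        beta_ols, *_ = np.linalg.lstsq(U, d.y, rcond=None)
        np.testing.assert_allclose(fit.beta_unpenalized, beta_ols, atol=1e-8)

    def test_lambda_zero_equals_full_least_squares(self):
        d, _ = _manual_design(50, 3, seed=0)
        fit = fit_null_model(d, ridge=0.0)
        Z = d.Z
        beta_z, *_ = np.linalg.lstsq(Z, d.y, rcond=None)
        got = np.concatenate([fit.beta_unpenalized, fit.gamma_ridge])
        np.testing.assert_allclose(got, beta_z, atol=1e-8)

    def test_huge_penalty_approaches_no_snp_fit(self, small_cohort):
        cohort, gm, _ = small_cohort
        d = build_design(cohort, gm, "volume")
        fit_big = fit_null_model(d, ridge=1e12)
        d0 = build_design(cohort, gm.select_snps([]), "volume")
        fit0 = fit_null_model(d0)
        assert np.abs(fit_big.gamma_ridge).max() < 1e-6
        np.testing.assert_allclose(
            fit_big.beta_unpenalized, fit0.beta_unpenalized, rtol=1e-6
        )

    def test_residuals_orthogonal_to_unpenalized_block(self, fitted_design):
        d, fit = fitted_design
        U = np.column_stack([d.X, d.E])
        assert np.abs(U.T @ fit.residuals).max() < 1e-6
        assert fit.sigma2_hat > 0

    def test_collinear_unpenalized_block_raises(self):
        d, _ = _manual_design(40, 2, seed=1)
        d.X = np.column_stack([d.X, d.X[:, 1]])
        d.x_names = d.x_names + ["sex_copy"]
        with pytest.raises(ValueError, match="collinear"):
            fit_null_model(d)


# ---------------------------------------------------------------------------
# burden test


class TestBurdenTest:
    def test_refit_oracle_large_n(self):
        """Score-test p agrees with the partial t-test from explicit refit."""
        cfg = scenario("burden", n_subjects=2000, n_snps=3, seed=5)
        cohort, gm, _ = simulate_cohort(cfg)
        d = build_design(cohort, gm, "volume")
        fit = fit_null_model(d, ridge=0.0)
        stat, p_score, degen = burden_gxe_score_test(fit, d)
        assert not degen
        s = d.E_centered * d.G.sum(axis=1)
        Z_aug = np.column_stack([d.Z, s])
        beta, *_ = np.linalg.lstsq(Z_aug, d.y, rcond=None)
        resid = d.y - Z_aug @ beta
        dof = d.n - Z_aug.shape[1]
        cov = (resid @ resid / dof) * np.linalg.pinv(Z_aug.T @ Z_aug)
        t = beta[-1] / np.sqrt(cov[-1, -1])
        p_refit = 2 * stats.t.sf(abs(t), dof)
        assert p_score == pytest.approx(p_refit, abs=1e-3)

    def test_burden_regressor_in_null_span_degenerate(self):
        d, _ = _manual_design(60, 2, seed=2)
        d.G = np.ones_like(d.G)  # G w proportional to intercept -> s = m*E_c in span(U)
        fit = fit_null_model(d, ridge=0.0)
        stat, p, degen = burden_gxe_score_test(fit, d)
        assert degen and p == 1.0 and stat == 0.0

    def test_constant_exposure_rejected(self, fitted_design):
        d, fit = fitted_design
        d.E = np.full(d.n, 8.0)
        with pytest.raises(ValueError, match="exposure"):
            burden_gxe_score_test(fit, d)


# ---------------------------------------------------------------------------
# variance-component test


class TestVarianceComponent:
    def test_zero_genotypes_give_p_one(self):
        d, _ = _manual_design(50, 4, seed=3)
        d.G = np.zeros_like(d.G)
        fit = fit_null_model(d, ridge=0.0)
        q, lam, p, method = variance_component_gxe_test(fit, d)
        assert q == 0.0 and p == 1.0

    def test_single_snp_matches_chi2_closed_form(self):
        """With m = 1 the mixture collapses to the squared standardized score."""
        cfg = scenario("null", n_subjects=2000, n_snps=1, seed=8)
        cohort, gm, _ = simulate_cohort(cfg)
        d = build_design(cohort, gm, "volume")
        fit = fit_null_model(d, ridge=0.0)
        q, lam, p_vc, _ = variance_component_gxe_test(fit, d)
        assert lam.size == 1
        c = d.E_centered * d.G[:, 0]
        mc = fit.apply_M(c)
        z2 = float(c @ fit.residuals) ** 2 / (fit.sigma2_hat * float(mc @ mc))
        # exact ratio form differs from the chi-square limit by O(1/n)
        assert p_vc == pytest.approx(stats.chi2.sf(z2, 1), abs=2e-3)

    def test_permutation_oracle(self):
        """p_vc agrees with a 200k residual-permutation reference."""
        cfg = scenario("null", n_subjects=120, n_snps=8, seed=12)
        cohort, gm, _ = simulate_cohort(cfg)
        d = build_design(cohort, gm, "volume")
        fit = fit_null_model(d)
        s = d.E_centered * d.G.sum(axis=1)
        q_obs, lam, p_vc, _ = variance_component_gxe_test(fit, d, orthogonalize_to=s)
        M = fit.M_matrix()
        r = fit.residuals
        yh_m = (d.y - r) @ M
        nu = d.n - fit.edf
        ms = M @ s
        u = ms / np.linalg.norm(ms)
        C = d.E_centered[:, None] * d.G
        rng = np.random.default_rng(99)
        n_perm, hits = 200_000, 0
        for start in range(0, n_perm, 4000):
            k = min(4000, n_perm - start)
            idx = rng.permuted(np.tile(np.arange(d.n), (k, 1)), axis=1)
            rf = yh_m[None, :] + r[idx] @ M
            s2 = (rf**2).sum(axis=1) / nu
            rf = rf - np.outer(rf @ u, u)
            q = ((rf @ C) ** 2).sum(axis=1) / (2 * s2)
            hits += int((q >= q_obs).sum())
        p_perm = (1 + hits) / (1 + n_perm)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_vc - p_perm) < 3 * se


# ---------------------------------------------------------------------------
# combination


class TestCombination:
    def test_both_one_gives_one(self):
        assert combine_fixed_and_vc(1.0, 1.0) == pytest.approx(1.0)

    def test_chi2_4_closed_form(self):
        x = -2 * (np.log(0.05) + np.log(0.05))
        expected = (1 + x / 2) * np.exp(-x / 2)
        assert combine_fixed_and_vc(0.05, 0.05) == pytest.approx(expected, rel=1e-10)

    def test_symmetry(self):
        assert combine_fixed_and_vc(0.01, 0.7) == pytest.approx(
            combine_fixed_and_vc(0.7, 0.01), rel=1e-12
        )

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            combine_fixed_and_vc(0.0, 0.5)


# ---------------------------------------------------------------------------
# orchestrated gene test and invariances


class TestGeneTest:
    def test_skipped_record_when_no_snps(self, small_cohort):
        cohort, gm, _ = small_cohort
        res = mixge_gene_test(cohort, gm.select_snps([]), GxEConfig(), gene_name="g")
        assert res.skipped and res.n_snps_tested == 0

    def test_result_fields_populated(self, small_cohort):
        from mixge import filter_hwe

        cohort, gm, _ = small_cohort
        res = mixge_gene_test(cohort, gm, GxEConfig(), gene_name="g")
        assert 0 < res.p_fixed <= 1 and 0 < res.p_vc <= 1 and 0 < res.p_combined <= 1
        kept, _ = filter_hwe(gm)
        assert res.n_snps_tested == kept.n_snps
        assert res.eigenvalues.size > 0

    def test_invariance_to_sex_recoding(self, small_cohort):
        cohort, gm, _ = small_cohort
        res1 = mixge_gene_test(cohort, gm, GxEConfig())
        flipped = cohort.assign(
            sex=np.where(cohort["sex"] == "male", "female", "male")
        )
        res2 = mixge_gene_test(flipped, gm, GxEConfig())
        for a, b in [
            (res1.p_fixed, res2.p_fixed),
            (res1.p_vc, res2.p_vc),
            (res1.p_combined, res2.p_combined),
        ]:
            assert a == pytest.approx(b, abs=1e-10)

    def test_invariance_to_dummy_reference(self):
        """Changing the dummy reference category leaves all p-values unchanged."""
        d1, _ = _manual_design(80, 5, seed=4, dummy_ref_first=True)
        d2, _ = _manual_design(80, 5, seed=4, dummy_ref_first=False)
        out = []
        for d in (d1, d2):
            fit = fit_null_model(d)
            _, pf, _ = burden_gxe_score_test(fit, d)
            s = d.E_centered * d.G.sum(axis=1)
            _, _, pv, _ = variance_component_gxe_test(fit, d, orthogonalize_to=s)
            out.append((pf, pv, combine_fixed_and_vc(pf, pv)))
        np.testing.assert_allclose(out[0], out[1], atol=1e-10)

    def test_invariance_to_outcome_units_and_exposure_centering(self, small_cohort):
        cohort, gm, _ = small_cohort
        base = mixge_gene_test(cohort, gm, GxEConfig())
        cm3 = cohort.assign(volume=cohort["volume"] / 1000.0)  # mm^3 -> cm^3
        res_units = mixge_gene_test(cm3, gm, GxEConfig())
        centered = cohort.assign(
            E_prenatal=cohort["E_prenatal"] - cohort["E_prenatal"].mean()
        )
        res_center = mixge_gene_test(centered, gm, GxEConfig())
        for res in (res_units, res_center):
            assert res.p_fixed == pytest.approx(base.p_fixed, abs=1e-10)
            assert res.p_vc == pytest.approx(base.p_vc, abs=1e-10)
            assert res.p_combined == pytest.approx(base.p_combined, abs=1e-10)
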