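"""Association engines: OLS oracle, GLS limits, deflation, calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist
from scipy.stats import kstest

from vertexlmm import (
    GeneratorConfig,
    MODEL_SPECS,
    MassUnivariateGLM,
    ModelSpec,
    ModelSuite,
    TraitSpec,
    VarianceComponents,
    build_atlas,
    compute_brm,
    fit_reml,
    generate_cohort,
    run_glm,
    run_lmm,
    simulate_null,
    simulate_trait,
    standardize_columns,
)
from vertexlmm.association import assemble_covariates


@pytest.fixture(scope="module")
def micro_cohort():
    """N=100, p=52 cohort for exact-refit comparisons."""
    cfg = GeneratorConfig(
        N=100,
        grid_dims={"ct": (3, 3), "ca": (3, 3), "st": (2, 2), "sa": (2, 2)},
        confounder_share=0.2,
        seed=41,
    )
    data, _ = generate_cohort(cfg)
    atlas = build_atlas(cfg)
    sdata = standardize_columns(data)
    return sdata, atlas, compute_brm(sdata)


class TestGLM:
    def test_normal_equations_oracle_with_covariate(self):
        """b and SE match an explicit (X'X)^-1 X'y regression at N=20."""
        rng = np.random.default_rng(2)
        n = 20
        x = rng.normal(size=n)
        cov = rng.normal(size=n)
        y = 0.7 * x + 0.3 * cov + rng.normal(size=n)
        X = ((x - x.mean()) / x.std())[:, None]
        data_vals = np.hstack([X, rng.normal(size=(n, 2))])
        est = MassUnivariateGLM().fit(data_vals, y, covariates=cov[:, None])

        D = np.column_stack([np.ones(n), cov, X[:, 0]])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        resid = y - D @ beta
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(D.T @ D)[2, 2])
        assert est.b_[0] == pytest.approx(beta[2], abs=1e-10)
        assert est.se_[0] == pytest.approx(se, abs=1e-10)
        assert est.chi2_[0] == pytest.approx((beta[2] / se) ** 2, rel=1e-10)

    def test_perfect_association_floors_pvalue(self, tiny_cohort, tiny_atlas):
        y = tiny_cohort.values[:, 3].copy()
        res = run_glm(y, tiny_cohort, ModelSpec("glm", "none"))
        assert res.pval[3] == np.finfo(np.float64).tiny
        assert np.sign(res.b[3]) == 1.0

    def test_orthogonal_phenotype_gives_zero_effect(self, tiny_cohort):
        x = tiny_cohort.values[:, 0]
        rng = np.random.default_rng(4)
        y = rng.normal(size=len(x))
        y -= (y @ x) / (x @ x) * x
        y -= y.mean()
        res = run_glm(y, tiny_cohort, ModelSpec("glm", "none"))
        assert abs(res.b[0]) < 1e-10
        assert res.chi2[0] < 1e-18

    def test_collinear_vertex_flagged_not_raised(self, tiny_cohort):
        vals = tiny_cohort.values.copy()
        cov = vals[:, 5].copy()
        data = tiny_cohort
        y = np.random.default_rng(6).normal(size=data.n_subjects)
        est = MassUnivariateGLM().fit(vals, y, covariates=cov[:, None])
        assert est.flagged_[5]
        assert est.chi2_[5] == 0.0
        assert est.pvalues_[5] == 1.0

    def test_subject_permutation_invariance(self, tiny_cohort, tiny_atlas):
        rng = np.random.default_rng(12)
        y = simulate_trait(tiny_cohort, TraitSpec(5, 0.4, seed=2), tiny_atlas).y
        res1 = run_glm(y, tiny_cohort, ModelSpec("glm", "none"))
        perm = rng.permutation(tiny_cohort.n_subjects)
        import dataclasses

        permuted = dataclasses.replace(
            tiny_cohort,
            values=tiny_cohort.values[perm],
            subject_id=[tiny_cohort.subject_id[i] for i in perm],
            covariates=tiny_cohort.covariates.iloc[perm].reset_index(drop=True),
        )
        res2 = run_glm(y[perm], permuted, ModelSpec("glm", "none"))
        np.testing.assert_allclose(res1.chi2, res2.chi2, rtol=1e-8)


class TestLMM:
    def test_zero_components_reduce_to_glm(self, tiny_cohort, tiny_atlas):
        y = simulate_trait(tiny_cohort, TraitSpec(5, 0.4, seed=5), tiny_atlas).y
        brm = compute_brm(tiny_cohort)
        vc = VarianceComponents(
            v_components=np.array([0.0]),
            v_e=1.0,
            morphometricity=0.0,
            se_morph=0.0,
            loglik=0.0,
            converged=True,
            n_iter=0,
        )
        lmm = run_lmm(y, tiny_cohort, MODEL_SPECS["lmm_global"], vc, [brm])
        glm = run_glm(y, tiny_cohort, ModelSpec("glm", "none"))
        np.testing.assert_allclose(lmm.chi2, glm.chi2, atol=1e-8)
        np.testing.assert_allclose(lmm.b, glm.b, atol=1e-8)

    def test_single_vertex_double_fitting_deflates_chi2(self):
        """p=1: the candidate IS the whole random effect, so its LMM test
        statistic must fall below the GLM one."""
        rng = np.random.default_rng(7)
        n = 200
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = 0.8 * x + rng.normal(size=n)
        y = (y - y.mean()) / y.std()
        data = __import__("vertexlmm").CohortMatrix(
            subject_id=[str(i) for i in range(n)],
            values=x[:, None],
            covariates=pd.DataFrame(index=range(n)),
            standardized=True,
            col_means=np.zeros(1),
            col_sds=np.ones(1),
        )
        brm = compute_brm(data)
        vc = fit_reml(y, None, [brm])
        assert vc.v_components[0] > 0  # the signal is in the BRM
        lmm = run_lmm(y, data, MODEL_SPECS["lmm_global"], vc, [brm])
        glm = run_glm(y, data, ModelSpec("glm", "none"))
        assert lmm.chi2[0] < glm.chi2[0]

    def test_one_pass_identical_to_gls_refit_at_fixed_components(self, micro_cohort):
        """At fixed variance components the one-pass scan IS the
        per-vertex GLS refit -- an algebraic identity the implementation
        must reproduce to numerical precision."""
        data, atlas, brm = micro_cohort
        trait = simulate_trait(data, TraitSpec(10, 0.5, seed=17), atlas)
        y = trait.y
        n = len(y)
        vc = fit_reml(y, None, [brm])
        res = run_lmm(y, data, MODEL_SPECS["lmm_global"], vc, [brm])
        V = vc.v_components[0] * brm.matrix + vc.v_e * np.eye(n)
        for i in np.argsort(res.chi2)[::-1][:5]:
            x = data.values[:, i]
            Z2 = np.column_stack([np.ones(n), x])
            W = Z2.T @ np.linalg.solve(V, Z2)
            coef = np.linalg.solve(W, Z2.T @ np.linalg.solve(V, y))
            se = np.sqrt(np.linalg.inv(W)[1, 1])
            assert res.chi2[i] == pytest.approx((coef[1] / se) ** 2, abs=1e-8)

    def test_one_pass_close_to_exact_reml_refit_oracle(self):
        """Against the exact oracle (vertex as fixed effect, REML
        re-estimated per candidate) the one-pass statistics are always
        deflated -- the double-fitting cost -- and agree to ~10% for the
        typical top vertex once per-vertex effects are small."""
        cfg = GeneratorConfig(
            N=400,
            grid_dims={"ct": (6, 5), "ca": (6, 5), "st": (3, 4), "sa": (3, 4)},
            confounder_share=0.2,
            seed=41,
        )
        raw, _ = generate_cohort(cfg)
        atlas = build_atlas(cfg)
        data = standardize_columns(raw)
        brm = compute_brm(data)
        n = data.n_subjects
        trait = simulate_trait(data, TraitSpec(50, 0.3, seed=17), atlas)
        y = trait.y
        vc = fit_reml(y, None, [brm])
        res = run_lmm(y, data, MODEL_SPECS["lmm_global"], vc, [brm])
        devs = []
        for i in np.argsort(res.chi2)[::-1][:10]:
            x = data.values[:, i]
            vc_i = fit_reml(y, x[:, None], [brm])
            V = vc_i.v_components[0] * brm.matrix + vc_i.v_e * np.eye(n)
            Z2 = np.column_stack([np.ones(n), x])
            W = Z2.T @ np.linalg.solve(V, Z2)
            coef = np.linalg.solve(W, Z2.T @ np.linalg.solve(V, y))
            se = np.sqrt(np.linalg.inv(W)[1, 1])
            chi2_exact = (coef[1] / se) ** 2
            assert res.chi2[i] <= chi2_exact + 1e-10  # deflation, never inflation
            devs.append(abs(res.chi2[i] / chi2_exact - 1.0))
        assert float(np.median(devs)) < 0.10

    def test_multi_brm_scan_runs_and_matches_global_when_tied(self, micro_cohort):
        data, atlas, brm = micro_cohort
        from vertexlmm import MEAS_TYPES

        brms = [compute_brm(data, subset=t, atlas=atlas) for t in MEAS_TYPES]
        trait = simulate_trait(data, TraitSpec(10, 0.5, seed=29), atlas)
        vc_g = fit_reml(trait.y, None, [brm])
        v, ve = vc_g.v_components[0], vc_g.v_e
        # with per-type variances fixed at the p-weighted split the dense
        # multi-BRM scan must equal the rotated single-BRM scan
        vc_m = VarianceComponents(
            v_components=np.array([v * b.p_used / data.n_vertices for b in brms]),
            v_e=ve,
            morphometricity=vc_g.morphometricity,
            se_morph=0.0,
            loglik=0.0,
            converged=True,
            n_iter=0,
        )
        res_g = run_lmm(trait.y, data, MODEL_SPECS["lmm_global"], vc_g, [brm])
        res_m = run_lmm(trait.y, data, MODEL_SPECS["lmm_multi_brm"], vc_m, brms)
        np.testing.assert_allclose(res_m.chi2, res_g.chi2, rtol=1e-8)


class TestSuite:
    def test_census_runs_all_eight_models(self, tiny_cohort, tiny_atlas):
        y = simulate_trait(tiny_cohort, TraitSpec(5, 0.4, seed=3), tiny_atlas).y
        suite = ModelSuite(tiny_cohort, tiny_atlas)
        results = suite.run(y)
        assert set(results) == set(MODEL_SPECS)
        assert len({r.n_subjects for r in results.values()}) == 1
        assert all(len(r) == tiny_cohort.n_vertices for r in results.values())
        assert all(np.all(r.chi2 >= 0) for r in results.values())
        assert all(
            np.all((r.pval > 0) & (r.pval <= 1)) for r in results.values()
        )

    def test_per_type_pc_set_has_forty_covariates(self, tiny_cohort, tiny_atlas):
        suite = ModelSuite(tiny_cohort, tiny_atlas)
        C = assemble_covariates(
            tiny_cohort, "pc10_per_type", pcs_per_type=suite.pcs_per_type
        )
        assert C.shape == (tiny_cohort.n_subjects, 40)

    def test_lmm_variance_components_attached(self, tiny_cohort, tiny_atlas):
        y = simulate_trait(tiny_cohort, TraitSpec(5, 0.6, seed=8), tiny_atlas).y
        res = ModelSuite(tiny_cohort, tiny_atlas, models=["lmm_global"]).run(y)
        assert res["lmm_global"].vc is not None
        assert 0 <= res["lmm_global"].vc.morphometricity <= 1


class TestNullCalibration:
    def test_pvalues_uniform_under_null(self, cohort_free):
        """Pooled over 20 null traits x 5000 vertices, GLM p-values are
        uniform (KS < 0.03); the mixed model matches on a subset."""
        data, atlas, brm = cohort_free
        suite = ModelSuite(data, atlas, models=["glm_no_covariates", "lmm_global"])
        glm_p, lmm_p = [], []
        for r in range(20):
            y = simulate_null(data.n_subjects, seed=4000 + r).y
            glm_p.append(suite.run_one(y, "glm_no_covariates").pval)
            if r < 5:
                lmm_p.append(suite.run_one(y, "lmm_global").pval)
        ks_glm = kstest(np.concatenate(glm_p), "uniform").statistic
        ks_lmm = kstest(np.concatenate(lmm_p), "uniform").statistic
        assert ks_glm < 0.03
        assert ks_lmm < 0.03

    def test_chi2_distribution_median_near_expected(self, cohort_free):
        data, atlas, _ = cohort_free
        suite = ModelSuite(data, atlas, models=["glm_no_covariates"])
        y = simulate_null(data.n_subjects, seed=4100).y
        res = suite.run_one(y, "glm_no_covariates")
        med = np.median(res.chi2)
        assert med == pytest.approx(chi2_dist.ppf(0.5, 1), rel=0.15)
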