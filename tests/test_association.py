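"""Association core: covariate adjustment, GWAS scan, patterns, multiplicity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from brainmr import (
    CollinearityError,
    GwasScan,
    PhenotypeTable,
    RegionalAssociation,
    RegionalVolumeMatrix,
    ValidationError,
    adjust_covariates,
    bh_fdr,
    bonferroni_threshold,
    genomic_inflation,
    gwas_scan,
    simulate_genotypes,
)
from brainmr.association import CHI2_MEDIAN_1DF, GwasResult


def _phen(df, categorical=(), ids=None):
    df = df.copy()
    if ids is None:
        ids = pd.Index([f"ind_{k:06d}" for k in range(len(df))], name="sample_id")
    df.index = ids
    return PhenotypeTable(df, frozenset(categorical))


class TestAdjustCovariates:
    def test_covariate_equal_to_response_zeroes_residuals(self):
        y = np.array([3.0, 1.0, 4.0, 1.5])
        resid, _ = adjust_covariates(y, pd.DataFrame({"c": y}))
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_covariate_leaves_centered_response(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        c = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to y and intercept
        resid, _ = adjust_covariates(y, pd.DataFrame({"c": c}))
        assert np.allclose(resid, y - y.mean(), atol=1e-10)

    def test_two_group_demeaning_closed_form(self):
        # y=(1,2,3,4) on group indicator (1,1,2,2): residuals demean per group
        resid, _ = adjust_covariates(
            np.array([1.0, 2.0, 3.0, 4.0]),
            pd.DataFrame({"g": [1.0, 1.0, 2.0, 2.0]}),
        )
        assert np.allclose(resid, [-0.5, 0.5, -0.5, 0.5], atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        y = rng.standard_normal(50)
        C = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        resid, keep = adjust_covariates(y, C)
        scale = np.abs(resid).max()
        for col in C.columns:
            assert abs(resid @ C[col].to_numpy()) < 1e-8 * max(scale, 1.0) * 50
        assert abs(resid.sum()) < 1e-8 * 50

    def test_collinear_design_names_columns(self, rng):
        c = rng.standard_normal(30)
        C = pd.DataFrame({"a": c, "b": 2 * c})
        with pytest.raises(CollinearityError) as err:
            adjust_covariates(rng.standard_normal(30), C)
        assert "b" in err.value.columns


class TestGwasScan:
    def test_matches_statsmodels_ols_exactly(self, rng):
        # full-rank oracle on a small instance, 1e-10 relative agreement
        n, m = 60, 8
        G = simulate_genotypes(n, m, rng.uniform(0.2, 0.5, m), seed=11)
        cov = pd.DataFrame(
            {"age": rng.normal(50, 5, n), "sex": rng.choice(["F", "M"], n)}
        )
        y = rng.standard_normal(n) + 0.3 * cov["age"].to_numpy() / 10
        P = _phen(pd.DataFrame({"y": y, **cov}), categorical=("sex",))
        res = GwasScan(G, P, "y", ("age", "sex")).fit()
        X_cov = np.column_stack(
            [np.ones(n), cov["age"], (cov["sex"] == "M").astype(float)]
        )
        for j in range(m):
            X = np.column_stack([G.dosages[:, j].astype(float), X_cov])
            fit = sm.OLS(y, X).fit()
            row = res.table.iloc[j]
            assert row["beta"] == pytest.approx(fit.params[0], rel=1e-10)
            assert row["se"] == pytest.approx(fit.bse[0], rel=1e-10)
            assert row["p"] == pytest.approx(fit.pvalues[0], rel=1e-8)

    def test_self_regression_recovers_unit_slope(self, rng):
        n = 500
        G = simulate_genotypes(n, 3, np.full(3, 0.4), seed=2)
        y = G.dosages[:, 1].astype(float) + rng.standard_normal(n) * 0.01
        res = gwas_scan(G, "y", (), _phen(pd.DataFrame({"y": y})))
        assert res.table["beta"].iloc[1] == pytest.approx(1.0, abs=0.01)

    def test_monomorphic_variant_flagged_missing(self):
        G = simulate_genotypes(200, 2, np.array([0.3, 1e-9]), seed=3)
        y = np.random.default_rng(0).standard_normal(200)
        res = gwas_scan(G, "y", (), _phen(pd.DataFrame({"y": y})))
        assert bool(res.table["monomorphic"].iloc[1])
        assert np.isnan(res.table["p"].iloc[1])
        assert np.isfinite(res.table["p"].iloc[0])

    def test_null_type_one_error_rate(self):
        # independent trait: ~5% of p-values below 0.05
        n, m = 300, 4000
        G = simulate_genotypes(n, m, np.random.default_rng(5).uniform(0.1, 0.5, m),
                               seed=5)
        y = np.random.default_rng(6).standard_normal(n)
        res = gwas_scan(G, "y", (), _phen(pd.DataFrame({"y": y})))
        frac = float((res.table["p"] < 0.05).mean())
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m)

    def test_missing_dosages_mean_imputed(self, rng):
        G = simulate_genotypes(100, 2, np.full(2, 0.4), seed=8)
        D = G.dosages.astype(float)
        D[:10, 0] = np.nan
        G.dosages = D
        y = rng.standard_normal(100)
        res = gwas_scan(G, "y", (), _phen(pd.DataFrame({"y": y})))
        assert np.isfinite(res.table["p"]).all()


class TestGenomicInflation:
    def _result_from_t(self, t):
        m = len(t)
        table = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(m)],
                "chrom": "1",
                "pos": np.arange(1, m + 1),
                "effect_allele": "A",
                "other_allele": "G",
                "beta": 0.0,
                "se": 1.0,
                "t": t,
                "p": np.full(m, 0.5),
                "n_used": 100,
            }
        )
        return GwasResult(table, "y", (), 100)

    def test_unit_lambda_at_null_median(self):
        t = np.full(11, np.sqrt(CHI2_MEDIAN_1DF))
        assert genomic_inflation(self._result_from_t(t))["lambda_gc"] == pytest.approx(1.0)

    def test_scale_equivariance_and_permutation_invariance(self, rng):
        t = rng.standard_normal(101)
        lam = genomic_inflation(self._result_from_t(t))["lambda_gc"]
        doubled = genomic_inflation(self._result_from_t(t * np.sqrt(2)))["lambda_gc"]
        shuffled = genomic_inflation(self._result_from_t(rng.permutation(t)))["lambda_gc"]
        assert doubled == pytest.approx(2 * lam)
        assert shuffled == pytest.approx(lam)

    def test_null_scan_lambda_near_one(self):
        n, m = 250, 20_000
        G = simulate_genotypes(n, m, np.random.default_rng(9).uniform(0.1, 0.5, m),
                               seed=9)
        y = np.random.default_rng(10).standard_normal(n)
        res = gwas_scan(G, "y", (), _phen(pd.DataFrame({"y": y})))
        assert 0.97 <= res.lambda_gc() <= 1.03


class TestRegionalAssociation:
    def test_constructed_effects_recovered_with_sign(self, rng):
        n, R = 800, 15
        trait = rng.standard_normal(n)
        c = np.linspace(-2, 2, R)
        V = 50 + np.outer(trait, c) + rng.standard_normal((n, R)) * 0.5
        ids = pd.Index([f"i{k}" for k in range(n)], name="sample_id")
        vol = RegionalVolumeMatrix(
            pd.DataFrame(V, index=ids, columns=[f"r{j}" for j in range(R)])
        )
        P = PhenotypeTable(pd.DataFrame({"d": trait}, index=ids))
        pat = RegionalAssociation(vol, P, "d").fit()
        big = np.abs(c) > 0.5
        assert np.array_equal(np.sign(pat.vector[big]), np.sign(c[big]))

    def test_null_pattern_centered(self, small_cohort, rng):
        P = small_cohort.phenotypes
        data = P.data.copy()
        data["noise"] = rng.standard_normal(len(data))
        P2 = PhenotypeTable(data, P.categorical)
        pat = RegionalAssociation(small_cohort.volumes, P2, "noise").fit()
        v = pat.vector
        assert abs(np.mean(v)) < 3 / np.sqrt(len(v))

    def test_std_beta_statistic_option(self, small_cohort):
        pat = RegionalAssociation(
            small_cohort.volumes, small_cohort.phenotypes, "coffee_intake",
            ("age",), statistic="std_beta",
        ).fit()
        assert "std_beta" in pat.table
        assert len(pat.vector) == 40


class TestMultiplicity:
    def test_bonferroni_paper_screen(self):
        assert bonferroni_threshold(0.05, 166, 17) == pytest.approx(0.05 / 166 / 17)
        assert bonferroni_threshold(0.05, 1, 1) == 0.05
        assert bonferroni_threshold(0.05, 166, 1) == pytest.approx(0.05 / 166)

    def test_bonferroni_invalid_inputs(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.0, 166, 17)
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0, 17)

    def test_bh_known_vectors(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_bh_nan_passthrough_and_validation(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])
        with pytest.raises(ValidationError):
            bh_fdr([0.0, 0.5])

    @staticmethod
    def _brute_force_rejections(p, alpha):
        # classic step-up: largest k with p_(k) <= k*alpha/m
        p = np.asarray(p)
        order = np.argsort(p)
        m = len(p)
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * alpha / m:
                k_max = k
        return set(order[:k_max])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12),
        st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_bh_rejection_set_matches_brute_force(self, p, alpha):
        q = bh_fdr(p)
        assert set(np.flatnonzero(q <= alpha)) == self._brute_force_rejections(p, alpha)
        assert np.all(q <= 1.0)
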