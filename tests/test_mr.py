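"""Bidirectional MR: pleiotropy pruning, verdict rule, IVW estimator."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from brainmr import (
    EmptyResultError,
    PrsModel,
    ValidationError,
    causal_verdict,
    ivw_estimate,
    remove_pleiotropy,
    stepwise_mr,
)
from brainmr.association import GwasResult
from brainmr.mr import DEFAULT_LADDER, MrReport
from brainmr.studies import _split_cohort
from brainmr import GwasScan, SimulationConfig, simulate_cohort


def _confound_gwas(variant_ids, p):
    m = len(variant_ids)
    table = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "effect_allele": "A",
            "other_allele": "G",
            "beta": 0.1,
            "se": 0.05,
            "t": 2.0,
            "p": p,
            "n_used": 100,
        }
    )
    return GwasResult(table, "confound", (), 100)


def _model(variant_ids, weights=None):
    return PrsModel(
        pd.DataFrame(
            {
                "variant_id": variant_ids,
                "effect_allele": "A",
                "weight": weights if weights is not None else 1.0,
            }
        ),
        p_threshold=0.05,
    )


class TestRemovePleiotropy:
    def test_threshold_partitions_variants(self):
        model = _model(["v0", "v1", "v2"])
        conf = _confound_gwas(["v0", "v1", "v2"], [0.01, 0.2, 0.6])
        assert list(remove_pleiotropy(model, conf, 0.05).entries["variant_id"]) == [
            "v1",
            "v2",
        ]
        assert list(remove_pleiotropy(model, conf, 0.25).entries["variant_id"]) == [
            "v2"
        ]

    def test_boundary_is_strict_inequality(self):
        model = _model(["v0"])
        conf = _confound_gwas(["v0"], [0.05])
        assert remove_pleiotropy(model, conf, 0.05).n_variants == 1

    def test_no_cross_association_leaves_model_unchanged(self):
        model = _model(["v0", "v1"])
        conf = _confound_gwas(["v0", "v1"], [1.0, 1.0])
        for t in DEFAULT_LADDER:
            assert remove_pleiotropy(model, conf, t).n_variants == 2

    def test_uncovered_variants_retained_and_counted(self):
        model = _model(["v0", "v9"])
        conf = _confound_gwas(["v0"], [0.01])
        pruned = remove_pleiotropy(model, conf, 0.05)
        assert list(pruned.entries["variant_id"]) == ["v9"]
        assert pruned.n_uncovered == 1

    def test_monotone_nesting_over_ladder(self, rng):
        ids = [f"v{j}" for j in range(40)]
        model = _model(ids)
        conf = _confound_gwas(ids, rng.uniform(0, 1, 40))
        prev = set(ids)
        for t in DEFAULT_LADDER:
            kept = set(remove_pleiotropy(model, conf, t).entries["variant_id"])
            assert kept <= prev
            prev = kept

    def test_full_removal_returns_flagged_empty_model(self):
        model = _model(["v0"])
        conf = _confound_gwas(["v0"], [1e-6])
        assert remove_pleiotropy(model, conf, 0.05).is_empty


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        out = ivw_estimate([0.5], [0.1], [0.1], [0.02])
        assert out["beta"] == pytest.approx(0.2)

    def test_duplicated_instrument_shrinks_se(self):
        one = ivw_estimate([0.5], [0.1], [0.1], [0.02])
        two = ivw_estimate([0.5, 0.5], [0.1, 0.1], [0.1, 0.1], [0.02, 0.02])
        assert two["beta"] == pytest.approx(one["beta"])
        assert two["se"] == pytest.approx(one["se"] / np.sqrt(2))

    def test_matches_wls_through_origin(self, rng):
        bx = rng.uniform(0.1, 0.5, 3)
        by = 0.3 * bx + rng.normal(0, 0.02, 3)
        sy = rng.uniform(0.01, 0.05, 3)
        out = ivw_estimate(bx, None, by, sy)
        wls = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        assert out["beta"] == pytest.approx(wls.params[0], rel=1e-10)
        # fixed-effect SE: unit-dispersion scale, not the WLS-estimated scale
        assert out["se"] == pytest.approx(
            float(np.sqrt(1.0 / np.sum(bx**2 / sy**2))), rel=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(EmptyResultError):
            ivw_estimate([], [], [], [])
        with pytest.raises(ValidationError):
            ivw_estimate([0.0, 0.0], None, [0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ValidationError):
            ivw_estimate([0.5], None, [0.1], [0.0])


def _report(fwd_p_out, rev_p_out, fwd_sign=1.0, rev_sign=1.0,
            fwd_p_exp=1e-6, rev_p_exp=1e-6):
    rows = []
    for direction, p_out, sign, p_exp in (
        ("X->Y", fwd_p_out, fwd_sign, fwd_p_exp),
        ("Y->X", rev_p_out, rev_sign, rev_p_exp),
    ):
        for i, t in enumerate(DEFAULT_LADDER):
            rows.append(
                {
                    "direction": direction,
                    "t": t,
                    "n_variants": 50 - i,
                    "r_exposure": 0.1,
                    "p_exposure": p_exp,
                    "r_outcome": sign * 0.02,
                    "p_outcome": p_out[i],
                }
            )
    return MrReport("x", "y", pd.DataFrame(rows))


class TestCausalVerdict:
    def test_forward_only_support(self):
        rep = _report([0.01] * 10, [0.5] * 10)
        assert causal_verdict(rep) == "X_causes_Y"

    def test_no_support_is_inconclusive(self):
        rep = _report([0.5] * 10, [0.6] * 10)
        assert causal_verdict(rep) == "inconclusive"

    def test_both_directions_supported(self):
        rep = _report([0.01] * 10, [0.02] * 10)
        assert causal_verdict(rep) == "bidirectional"

    def test_partial_support_needs_lower_min_frac(self):
        # 7 of 10 rows significant with consistent sign: the strict
        # all-rows tier withholds support, the lenient tier grants it
        p = [0.01] * 7 + [0.08] * 3
        rep = _report(p, [0.5] * 10)
        assert causal_verdict(rep, min_frac=1.0) == "inconclusive"
        assert causal_verdict(rep, min_frac=0.5) == "X_causes_Y"

    def test_inconsistent_sign_blocks_support(self):
        rows_p = [0.01] * 10
        rep = _report(rows_p, [0.5] * 10)
        rep.table.loc[3, "r_outcome"] *= -1
        assert causal_verdict(rep) == "inconclusive"

    def test_failed_instrument_validity_blocks_support(self):
        rep = _report([0.01] * 10, [0.5] * 10, fwd_p_exp=0.2)
        assert causal_verdict(rep) == "inconclusive"

    def test_sparse_ladder_forces_inconclusive(self):
        rep = _report([0.01] * 10, [0.5] * 10)
        fwd = rep.table["direction"] == "X->Y"
        rep.table.loc[fwd, "n_variants"] = [50, 40, 0, 0, 0, 0, 0, 0, 0, 0]
        assert causal_verdict(rep) == "inconclusive"

    def test_nonincreasing_count_invariant_enforced(self):
        rep_rows = _report([0.01] * 10, [0.5] * 10).table.copy()
        rep_rows.loc[2, "n_variants"] = 500
        with pytest.raises(ValidationError):
            MrReport("x", "y", rep_rows)


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(
        n_individuals=8000, n_snps=400, n_causal_x=50, n_causal_y=50,
        n_shared=10, n_causal_vol=50, n_pleiotropic_vol=5, n_regions=30,
        n_genes=20, n_signal_genes=3, causal_beta_xy=-0.15, seed=77,
    )
    cohort = simulate_cohort(cfg)
    (G_d, P_d), (G_t, P_t) = _split_cohort(cohort)
    covs = ("age", "sex", "site")
    x_gwas = GwasScan(G_d, P_d, "coffee_intake", covs).fit()
    y_gwas = GwasScan(G_d, P_d, "total_gmv", covs).fit()
    return stepwise_mr(
        G_t, P_t, x_gwas, y_gwas, "coffee_intake", "total_gmv", covs
    )


class TestStepwiseMr:
    def test_report_shape(self, fitted):
        for direction in ("X->Y", "Y->X"):
            ladder = fitted.direction_rows(direction)
            assert len(ladder) == 10
            raw = fitted.direction_rows(direction, ladder_only=False)
            assert raw["t"].isna().sum() == 1

    def test_instrument_counts_nonincreasing(self, fitted):
        for direction in ("X->Y", "Y->X"):
            counts = fitted.direction_rows(direction)["n_variants"].to_numpy()
            assert np.all(np.diff(counts) <= 0)

    def test_exposure_validity_strong_in_forward_direction(self, fitted):
        fwd = fitted.direction_rows("X->Y")
        assert (fwd["p_exposure"] < 1e-3).all()

    def test_metadata_stamps_two_sample_assertion(self, fitted):
        assert fitted.metadata["discovery_disjoint_asserted"]
        assert len(fitted.metadata["target_sample_hash"]) == 16

    def test_summary_mentions_both_verdict_tiers(self, fitted):
        s = fitted.summary()
        assert "strict" in s and "lenient" in s

    def test_caller_must_assert_disjointness(self, fitted, small_cohort):
        from brainmr import BidirectionalMR

        with pytest.raises(ValidationError):
            BidirectionalMR(
                small_cohort.genotypes,
                small_cohort.phenotypes,
                "coffee_intake",
                "bmi",
                None,
                None,
                discovery_disjoint=False,
            )

    def test_prune_against_flat_confound_reproduces_raw_rows(self):
        # with a confound GWAS reporting p=1 everywhere, the valid-PRS
        # equals the raw PRS at every removal threshold
        cfg = SimulationConfig(
            n_individuals=3000, n_snps=150, n_causal_x=20, n_causal_y=20,
            n_shared=4, n_causal_vol=0, h2_vol=0.0, n_pleiotropic_vol=0,
            n_regions=15, n_genes=10, n_signal_genes=2, seed=5,
        )
        cohort = simulate_cohort(cfg)
        (G_d, P_d), (G_t, P_t) = _split_cohort(cohort)
        x_gwas = GwasScan(G_d, P_d, "coffee_intake", ("age",)).fit()
        flat = x_gwas.table.copy()
        flat["p"] = 1.0
        y_flat = GwasResult(flat, "total_gmv", ("age",), x_gwas.n_used)
        rep = stepwise_mr(
            G_t, P_t, x_gwas, y_flat, "coffee_intake", "total_gmv", ("age",)
        )
        rows = rep.direction_rows("X->Y", ladder_only=False)
        raw = rows[rows["t"].isna()].iloc[0]
        ladder = rows[rows["t"].notna()]
        assert (ladder["n_variants"] == raw["n_variants"]).all()
        assert np.allclose(ladder["r_outcome"], raw["r_outcome"])
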