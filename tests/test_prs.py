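"""PRS engine: greedy clumping, threshold selection, harmonized scoring."""

import numpy as np
import pandas as pd
import pytest

from brainmr import (
    AlleleMismatchError,
    GenotypeMatrix,
    PhenotypeTable,
    PrsModel,
    ValidationError,
    build_prs,
    clump,
    score,
    simulate_cohort,
    simulate_genotypes,
    SimulationConfig,
)
from brainmr.association import GwasResult, gwas_scan


def _gwas_result(variants, p, beta=None, n=100):
    m = len(p)
    table = pd.DataFrame(
        {
            "variant_id": variants["variant_id"],
            "chrom": variants["chrom"],
            "pos": variants["pos"],
            "effect_allele": variants["effect_allele"],
            "other_allele": variants["other_allele"],
            "beta": beta if beta is not None else np.ones(m),
            "se": 1.0,
            "t": 1.0,
            "p": p,
            "n_used": n,
        }
    )
    return GwasResult(table, "trait", (), n)


def _panel(dosages, positions=None, effect=None, other=None):
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": positions if positions is not None else 1 + 1000 * np.arange(m),
            "effect_allele": effect if effect is not None else ["A"] * m,
            "other_allele": other if other is not None else ["G"] * m,
        }
    )
    ids = pd.Index([f"i{k}" for k in range(n)], name="sample_id")
    return GenotypeMatrix(ids, variants, dosages)


class TestClump:
    def test_greedy_rule_claims_linked_neighbor(self, rng):
        n = 400
        v1 = rng.binomial(2, 0.4, n).astype(float)
        v2 = v1.copy()
        v2[:20] = rng.binomial(2, 0.4, 20)  # r2 ~ 0.9 with v1
        v3 = rng.binomial(2, 0.4, n).astype(float)
        G = _panel(np.column_stack([v1, v2, v3]), positions=[100, 200, 300_000_000])
        res = _gwas_result(G.variants, [1e-10, 1e-8, 1e-9])
        leads = clump(res, G, r2_max=0.5, window_kb=250, p_index=5e-8)
        assert leads == ["v0", "v2"]  # v0 wins on p, claims linked v1; v2 unlinked

    def test_index_threshold_excludes_suggestive_variant(self, rng):
        G = _panel(rng.binomial(2, 0.3, (100, 2)).astype(float))
        res = _gwas_result(G.variants, [1e-9, 1e-7])
        assert clump(res, G, p_index=5e-8) == ["v0"]

    def test_no_candidates_returns_empty(self, rng):
        G = _panel(rng.binomial(2, 0.3, (50, 3)).astype(float))
        res = _gwas_result(G.variants, [0.5, 0.2, 0.9])
        assert clump(res, G) == []

    def test_ld_free_panel_keeps_every_significant_variant(self):
        # unlinked variants: leads == the p <= p_index set for any r2_max
        m = 30
        G = simulate_genotypes(2000, m, np.random.default_rng(3).uniform(0.2, 0.5, m),
                               seed=3)
        p = np.random.default_rng(4).uniform(0, 1, m)
        p[:7] = 1e-9
        res = _gwas_result(G.variants, p)
        expected = set(res.table.loc[p <= 5e-8, "variant_id"])
        for r2_max in (0.05, 0.1, 0.5):
            assert set(clump(res, G, r2_max=r2_max)) == expected

    def test_tie_break_prefers_smaller_coordinate(self, rng):
        G = _panel(rng.binomial(2, 0.3, (200, 3)).astype(float),
                   positions=[100, 5_000_000, 9_000_000])
        # equal p everywhere: leads emerge in genomic-coordinate order
        res = _gwas_result(G.variants, [1e-9, 1e-9, 1e-9])
        assert clump(res, G, window_kb=1) == ["v0", "v1", "v2"]


class TestBuildPrs:
    def test_threshold_selection_counts(self, rng):
        G = _panel(rng.binomial(2, 0.3, (50, 3)).astype(float))
        res = _gwas_result(G.variants, [1e-9, 0.03, 0.2])
        assert build_prs(res, 0.05).n_variants == 2
        assert build_prs(res, 1.0).n_variants == 3

    def test_empty_selection_is_flagged_model(self, rng):
        G = _panel(rng.binomial(2, 0.3, (50, 2)).astype(float))
        res = _gwas_result(G.variants, [0.5, 0.9])
        model = build_prs(res, 0.05)
        assert model.is_empty

    def test_null_gwas_selection_rate(self):
        n, m = 400, 4000
        G = simulate_genotypes(n, m, np.random.default_rng(12).uniform(0.1, 0.5, m),
                               seed=12)
        y = np.random.default_rng(13).standard_normal(n)
        P = PhenotypeTable(pd.DataFrame({"y": y}, index=G.sample_ids))
        model = build_prs(gwas_scan(G, "y", (), P), 0.05)
        assert abs(model.n_variants - 0.05 * m) < 3 * np.sqrt(0.05 * 0.95 * m)


class TestScore:
    def test_single_entry_dosage_scaling(self):
        G = _panel(np.array([[0.0], [1.0], [2.0]]))
        model = PrsModel(
            pd.DataFrame(
                {"variant_id": ["v0"], "effect_allele": ["A"], "weight": [0.5]}
            ),
            p_threshold=0.05,
        )
        assert list(score(model, G)) == [0.0, 0.5, 1.0]

    def test_allele_flip_reflects_dosage(self):
        G = _panel(np.array([[2.0], [0.0]]))  # effect A, other G
        model = PrsModel(
            pd.DataFrame(
                {"variant_id": ["v0"], "effect_allele": ["G"], "weight": [0.5]}
            ),
            p_threshold=0.05,
        )
        # weight on the other allele: dosage 2 -> 0.5*(2-2)=0, dosage 0 -> 1.0
        assert list(score(model, G)) == [0.0, 1.0]

    def test_flip_consistency_whole_model(self, rng):
        n, m = 300, 12
        G = simulate_genotypes(n, m, rng.uniform(0.2, 0.5, m), seed=6)
        w = rng.standard_normal(m)
        entries = pd.DataFrame(
            {
                "variant_id": G.variants["variant_id"],
                "effect_allele": G.variants["effect_allele"],
                "weight": w,
            }
        )
        flipped = entries.copy()
        half = m // 2
        flipped.loc[:half, "effect_allele"] = G.variants.loc[:half, "other_allele"]
        flipped.loc[:half, "weight"] = -w[: half + 1]
        s1 = score(PrsModel(entries, 0.05), G)
        s2 = score(PrsModel(flipped, 0.05), G)
        # representing a variant on either allele shifts the score by a
        # constant (2 * weight) but never changes contrasts between people
        diff = s1 - s2
        assert np.allclose(diff - diff.iloc[0], 0.0, atol=1e-10)
        assert np.corrcoef(s1, s2)[0, 1] == pytest.approx(1.0)

    def test_variant_order_invariance(self, rng):
        n, m = 100, 8
        G = simulate_genotypes(n, m, rng.uniform(0.2, 0.5, m), seed=7)
        entries = pd.DataFrame(
            {
                "variant_id": G.variants["variant_id"],
                "effect_allele": G.variants["effect_allele"],
                "weight": rng.standard_normal(m),
            }
        )
        shuffled = entries.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert np.allclose(
            score(PrsModel(entries, 0.05), G), score(PrsModel(shuffled, 0.05), G)
        )

    def test_unresolvable_allele_mismatch_lists_variants(self):
        G = _panel(np.array([[1.0]]))
        model = PrsModel(
            pd.DataFrame(
                {"variant_id": ["v0"], "effect_allele": ["T"], "weight": [1.0]}
            ),
            p_threshold=0.05,
        )
        with pytest.raises(AlleleMismatchError) as err:
            score(model, G)
        assert "v0" in err.value.variant_ids

    def test_true_weight_score_correlation_matches_heritability(self):
        cfg = SimulationConfig(n_individuals=20_000, n_snps=500, n_causal_x=60,
                               n_causal_y=60, n_shared=10, n_causal_vol=0,
                               h2_vol=0.0, n_pleiotropic_vol=0, n_regions=15,
                               n_genes=10, n_signal_genes=2, seed=31)
        c = simulate_cohort(cfg)
        truth = c.truth["beta_y"]
        mafs = c.genotypes.allele_frequencies()
        sd = np.sqrt(2 * mafs * (1 - mafs))
        entries = pd.DataFrame(
            {
                "variant_id": list(truth),
                "effect_allele": c.genotypes.variants.set_index("variant_id").loc[
                    list(truth), "effect_allele"
                ].to_numpy(),
                # per-dosage weights equivalent to standardized-scale effects
                "weight": [
                    truth[v] / sd[c.genotypes.variant_index().get_loc(v)]
                    for v in truth
                ],
            }
        )
        s = score(PrsModel(entries, 1.0), c.genotypes)
        r = np.corrcoef(s, c.phenotypes.data["coffee_intake"])[0, 1]
        se = (1 - cfg.h2_y) / np.sqrt(cfg.n_individuals)
        assert abs(r - np.sqrt(cfg.h2_y)) < max(3 * se, 0.02)


class TestSerialization:
    def test_model_round_trip_with_sidecar(self, tmp_path, rng):
        entries = pd.DataFrame(
            {
                "variant_id": ["v0", "v1"],
                "effect_allele": ["A", "C"],
                "weight": [0.5, -0.25],
                "p": [0.01, 0.04],
            }
        )
        model = PrsModel(entries, 0.05, provenance="gwas:coffee",
                         pruned_against=[("total_gmv", 0.1)])
        model.to_tsv(tmp_path / "m.tsv", sidecar=tmp_path / "m.yaml")
        back = PrsModel.from_tsv(tmp_path / "m.tsv", sidecar=tmp_path / "m.yaml")
        assert back.p_threshold == 0.05
        assert back.pruned_against == [("total_gmv", 0.1)]
        pd.testing.assert_frame_equal(back.entries, entries)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValidationError):
            PrsModel(
                pd.DataFrame(
                    {"variant_id": ["v0"], "effect_allele": ["A"], "weight": [1.0]}
                ),
                p_threshold=0.0,
            )
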