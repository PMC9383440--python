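"""Replicated simulation studies of the pipeline's operating characteristics.

Each function runs a self-contained study — direction recovery of the
bidirectional MR, IVW unbiasedness and coverage, permutation-test
calibration and power, proportion-mediated recovery, and excess-PM mediator
selection — on cohorts drawn by :mod:`brainmr.simulate`, and returns the
measured rates.  Problem sizes default to the desk-scale study conditions
described in docs/methods.md; everything is driven by one seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import GwasScan
from .containers import GenotypeMatrix, PhenotypeTable, RegionalVolumeMatrix
from .mediation import MediationModel, excess_pm
from .mr import BidirectionalMR, ivw_estimate
from .patterns import PatternSimilarity
from .simulate import SimulationConfig, simulate_cohort, simulate_genotypes
from .simulate import simulate_mediation_triple

_COVS = ("age", "sex", "site")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _split_cohort(cohort):
    """Disjoint discovery/target halves sharing the variant panel."""
    n = cohort.genotypes.n_samples
    half = n // 2
    out = []
    for sl in (slice(0, half), slice(half, n)):
        ids = cohort.genotypes.sample_ids[sl]
        G = GenotypeMatrix(
            ids, cohort.genotypes.variants.copy(), cohort.genotypes.dosages[sl]
        )
        data = cohort.phenotypes.data.loc[ids].copy()
        data["total_gmv"] = cohort.volumes.data.loc[ids].sum(axis=1)
        out.append((G, PhenotypeTable(data, cohort.phenotypes.categorical)))
    return out


def mr_direction_replicate(seed: int, n_per_sample: int = 20_000, **config_kwargs):
    """One two-sample MR replicate under the default X->Y causal conditions.

    Simulates a single cohort of ``2 * n_per_sample`` individuals and splits
    it into a discovery half (GWAS of exposure and outcome) and a target
    half (instrument association tests), mirroring the batch-split design
    of running discovery and instrument testing in disjoint samples.
    """
    cfg = SimulationConfig(n_individuals=2 * n_per_sample, seed=seed, **config_kwargs)
    cohort = simulate_cohort(cfg)
    (G_d, P_d), (G_t, P_t) = _split_cohort(cohort)
    x_gwas = GwasScan(G_d, P_d, "coffee_intake", _COVS, dtype=np.float32).fit()
    y_gwas = GwasScan(G_d, P_d, "total_gmv", _COVS, dtype=np.float32).fit()
    return BidirectionalMR(
        G_t, P_t, "coffee_intake", "total_gmv", x_gwas, y_gwas, covariates=_COVS
    ).fit()


def mr_direction_study(
    n_replicates: int = 50, seed: int = 0, n_per_sample: int = 20_000
) -> pd.DataFrame:
    """Direction recovery over replicated cohorts with a known causal path.

    Returns one row per replicate: the verdict, how many ladder rows were
    outcome-significant in each direction, and whether the reverse-direction
    (outcome-PRS vs exposure) association stayed nonsignificant at every
    removal threshold — the valid-PRS asymmetry the design is meant to
    produce.
    """
    rows = []
    for s in _child_seeds(seed, n_replicates):
        rep = mr_direction_replicate(s, n_per_sample)
        fwd = rep.direction_rows("X->Y")
        rev = rep.direction_rows("Y->X")
        rows.append(
            {
                "seed": s,
                "verdict": rep.verdict,
                "fwd_sig_rows": int((fwd["p_outcome"] < 0.05).sum()),
                "rev_sig_rows": int((rev["p_outcome"] < 0.05).sum()),
                "rev_all_nonsig": bool((rev["p_outcome"] >= 0.05).all()),
            }
        )
    return pd.DataFrame(rows)


def ivw_study(
    n_sims: int = 200,
    seed: int = 0,
    true_beta: float = 0.3,
    n_instruments: int = 20,
    h2: float = 0.4,
    n_discovery: int = 50_000,
    n_target: int = 10_000,
) -> dict:
    """Two-sample IVW with valid instruments: bias and CI coverage.

    Every instrument is truly causal for the exposure with equal variance
    share, so the exclusion restriction holds by construction; discovery
    effects come from a GWAS in one sample and outcome effects from an
    independent sample.
    """
    seeds = _child_seeds(seed, n_sims)
    est, ses, covered = [], [], 0
    m = n_instruments
    for s in seeds:
        rng = np.random.default_rng(s)
        mafs = rng.uniform(0.1, 0.5, m)
        beta = np.sqrt(h2 / m) * rng.choice([-1.0, 1.0], m)
        G1 = simulate_genotypes(n_discovery, m, mafs, seed=s + 1)
        G2 = simulate_genotypes(n_target, m, mafs, seed=s + 2)
        sd = np.sqrt(2 * mafs * (1 - mafs))

        def polygenic(G):
            return ((G.dosages - 2 * mafs) / sd) @ beta

        x1 = polygenic(G1) + rng.standard_normal(n_discovery) * np.sqrt(1 - h2)
        x2 = polygenic(G2) + rng.standard_normal(n_target) * np.sqrt(1 - h2)
        y2 = true_beta * x2 + rng.standard_normal(n_target) * np.sqrt(
            1 - true_beta**2
        )
        P1 = PhenotypeTable(pd.DataFrame({"x": x1}, index=G1.sample_ids))
        P2 = PhenotypeTable(pd.DataFrame({"y": y2}, index=G2.sample_ids))
        xg = GwasScan(G1, P1, "x").fit()
        yg = GwasScan(G2, P2, "y").fit()
        iv = ivw_estimate(
            xg.table["beta"], xg.table["se"], yg.table["beta"], yg.table["se"]
        )
        est.append(iv["beta"])
        ses.append(iv["se"])
        covered += abs(iv["beta"] - true_beta) < 1.96 * iv["se"]
    est = np.asarray(est)
    return {
        "true_beta": true_beta,
        "mean_beta": float(est.mean()),
        "sd_beta": float(est.std(ddof=1)),
        "se_of_mean": float(est.std(ddof=1) / np.sqrt(n_sims)),
        "coverage": covered / n_sims,
        "n_sims": n_sims,
    }


def _pattern_pair_dataset(
    n: int, n_regions: int, effect_scale: float, r_true: float, seed: int
):
    """Two traits with planted regional effect patterns of exact sample
    correlation ``r_true`` (zero scale gives the global null)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    age = rng.normal(55.0, 7.5, n)
    c = rng.standard_normal(n_regions)
    e = rng.standard_normal(n_regions)
    c = (c - c.mean()) / c.std()
    e = e - e.mean()
    e -= (e @ c) / (c @ c) * c  # exact orthogonalization
    e /= e.std()
    d = r_true * c + np.sqrt(1 - r_true**2) * e
    vols = 100.0 + effect_scale * (np.outer(a, c) + np.outer(b, d))
    vols += rng.standard_normal((n, n_regions))
    ids = pd.Index([f"i{i}" for i in range(n)], name="sample_id")
    V = RegionalVolumeMatrix(
        pd.DataFrame(vols, index=ids, columns=[f"r{j}" for j in range(n_regions)])
    )
    P = PhenotypeTable(
        pd.DataFrame({"trait_a": a, "trait_b": b, "age": age}, index=ids)
    )
    return V, P


def permutation_calibration_study(
    n_replicates: int = 500,
    seed: int = 0,
    n: int = 200,
    n_regions: int = 40,
    n_perm: int = 199,
) -> np.ndarray:
    """Permutation p-values under the global null (no trait-volume effect)."""
    out = np.empty(n_replicates)
    for i, s in enumerate(_child_seeds(seed, n_replicates)):
        V, P = _pattern_pair_dataset(n, n_regions, 0.0, 0.0, s)
        res = PatternSimilarity(V, P, ("age",)).pair_test(
            "trait_a", "trait_b", n_perm=n_perm, seed=s + 1
        )
        out[i] = res.p_perm
    return out


def permutation_power_study(
    n_replicates: int = 60,
    seed: int = 0,
    n: int = 2000,
    n_regions: int = 40,
    n_perm: int = 999,
    r_true: float = 0.6,
    alpha: float = 0.05,
) -> float:
    """Detection rate for a planted cross-trait effect-pattern correlation.

    The per-region effect scale is set so the trait term reaches |t| of
    about 8 on a typical region, a strong but realistic spatial signal.
    """
    effect_scale = 8.0 / np.sqrt(n)
    hits = 0
    for s in _child_seeds(seed, n_replicates):
        V, P = _pattern_pair_dataset(n, n_regions, effect_scale, r_true, s)
        res = PatternSimilarity(V, P, ("age",)).pair_test(
            "trait_a", "trait_b", n_perm=n_perm, seed=s + 1
        )
        hits += res.p_perm < alpha
    return hits / n_replicates


def pm_recovery_study(
    n_replicates: int = 20,
    seed: int = 0,
    n: int = 100_000,
    a: float = 0.3,
    b: float = 0.4,
    c_prime: float = 0.12,
) -> dict:
    """Proportion-mediated point estimates on replicated standardized chains."""
    pms = []
    for s in _child_seeds(seed, n_replicates):
        df = simulate_mediation_triple(a, b, c_prime, n, seed=s)
        pms.append(MediationModel(df, "g", "m", "y").fit().pm)
    true_pm = a * b / (a * b + c_prime)
    return {
        "true_pm": true_pm,
        "median_pm": float(np.median(pms)),
        "pm_estimates": pms,
        "n_replicates": n_replicates,
    }


def excess_pm_study(
    n_replicates: int = 50,
    seed: int = 0,
    n: int = 20_000,
    n_boot: int = 500,
    a: float = 0.3,
    b: float = 0.4,
    c_prime: float = 0.12,
) -> dict:
    """Mediator selection on SNP -> diet -> metabolic-trait chains.

    Model A uses the true mediator; model B is the reversed (wrong) model
    with the outcome as mediator.  Reports how often the true mediator is
    preferred by the excess-PM bootstrap.
    """
    preferred_correct = 0
    excesses = []
    for s in _child_seeds(seed, n_replicates):
        df = simulate_mediation_triple(a, b, c_prime, n, seed=s)
        A = MediationModel(df, "g", "m", "y")
        B = MediationModel(df, "g", "y", "m")
        res = excess_pm(A, B, n_boot=n_boot, seed=s + 1)
        preferred_correct += res.preferred == "m"
        excesses.append(res.excess)
    return {
        "correct_rate": preferred_correct / n_replicates,
        "mean_excess": float(np.mean(excesses)),
        "n_replicates": n_replicates,
    }


def ks_uniform_p(p_values: np.ndarray) -> float:
    """Kolmogorov–Smirnov p for uniformity of a p-value sample on (0, 1)."""
    return float(stats.kstest(p_values, "uniform").pvalue)
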