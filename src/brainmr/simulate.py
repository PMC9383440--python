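"""Synthetic cohort generation with known ground truth.

The generator emulates the statistical structure of a diet–brain imaging
genetics study: biallelic SNPs in Hardy–Weinberg proportions; two
anticorrelated polygenic diet phenotypes (a cereal-like trait ``x`` and a
coffee-like trait ``y``) that share pleiotropic variants with exactly
opposite-sign effects; a causal path from diet ``y`` to total gray-matter
volume distributed over atlas regions through a spatially structured loading
pattern; a direct polygenic component of brain volume (with an optional
pleiotropic contamination of the diet-``y`` variants, which is what the MR
pleiotropy-pruning stage must remove); SNP -> diet -> metabolic-trait
mediation chains with configurable standardized paths (a, b, c'); and a
gene-by-region expression matrix containing genes whose spatial profile
correlates with the regional effect pattern at a configurable level.

All effects are additive-linear and variants are drawn independently by
default (an optional AR(1) block-LD mode exists solely to exercise clumping).
One master seed drives deterministic per-component child seeds, so an
identical :class:`SimulationConfig` reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    RegionalVolumeMatrix,
)
from .exceptions import ValidationError

_BASES = np.array(list("ACGT"))

# fixed covariate effects (not config-tunable): plausible desk-scale magnitudes
_AGE_MEAN, _AGE_SD = 55.1, 7.46
_P_FEMALE = 0.524
_SITE_PROBS = {"site_A": 0.845, "site_B": 0.155}
_DIET_AGE_EFF = -0.005  # SD of intake per year of age
_DIET_SEX_EFF = 0.05  # male minus female offset, SD units
_DIET_SITE_EFF = 0.02  # site_B offset
_VOL_AGE_EFF = -2.0  # mm^3 per region per year (aging-related shrinkage)
_VOL_SEX_EFF = 8.0  # male minus female, mm^3 per region
_VOL_SITE_EFF = 5.0  # site_B scanner offset, mm^3 per region
_LIFESTYLE_B, _LIFESTYLE_CPRIME = 0.2, 0.02  # alcohol-frequency chain


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    Attributes
    ----------
    n_individuals, n_snps : cohort and panel sizes.
    maf_range : minor-allele-frequency range, both ends in (0, 1).
    n_causal_x, n_causal_y : causal variant counts for diet x (cereal-like)
        and diet y (coffee-like); ``n_shared`` of them are pleiotropic with
        exactly opposite-sign effects on the two diets.
    h2_x, h2_y : narrow-sense heritabilities of the diets, in [0, 1).
    causal_beta_xy : standardized causal effect of diet y on total
        gray-matter volume (SD of TGMV per SD of intake).
    n_causal_vol, h2_vol : direct polygenic component of brain volume
        (variants disjoint from the diet sets), as a fraction of the
        covariate-adjusted TGMV variance.
    n_pleiotropic_vol : number of diet-y causal variants that additionally
        carry direct volume effects — true exclusion-restriction violations
        that the MR pruning ladder must strip out.
    n_regions : atlas size (166 by default).
    region_effect_pattern : optional per-region loading vector; drawn as a
        lobe-structured random pattern when omitted.
    region_noise_sd : per-region volume noise SD (volume units).
    mediation_params : standardized paths (a, b, c') of the
        SNP -> diet_y -> BMI chain; true PM = ab / (ab + c').
    n_genes, n_signal_genes, expression_r : expression matrix size, number
        of genes whose regional profile correlates with the effect pattern,
        and the target correlation.
    ld_rho, ld_block_size : optional AR(1) latent-allele correlation within
        fixed-size variant blocks (defaults give independent variants).
    round_diets : emit intakes rounded to integer bowls/cups instead of the
        default continuous measures.
    seed : master seed; child seeds are spawned deterministically.
    """

    n_individuals: int = 20_000
    n_snps: int = 2_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_x: int = 200
    n_causal_y: int = 200
    n_shared: int = 20
    h2_x: float = 0.2
    h2_y: float = 0.2
    causal_beta_xy: float = -0.1
    n_causal_vol: int = 200
    h2_vol: float = 0.2
    n_pleiotropic_vol: int = 20
    n_regions: int = 166
    region_effect_pattern: np.ndarray | None = None
    region_noise_sd: float = 60.0
    region_baseline_range: tuple[float, float] = (2500.0, 5500.0)
    mediation_params: tuple[float, float, float] = (0.1, 0.3, 0.03)
    n_genes: int = 500
    n_signal_genes: int = 20
    expression_r: float = 0.6
    ld_rho: float = 0.0
    ld_block_size: int = 1
    round_diets: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError(f"maf_range must lie within (0,1), got {self.maf_range}")
        for name in ("h2_x", "h2_y", "h2_vol"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"{name} must be in [0,1), got {v}")
        for name in ("n_individuals", "n_snps", "n_regions", "n_genes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.n_shared > min(self.n_causal_x, self.n_causal_y):
            raise ValidationError("n_shared exceeds min(n_causal_x, n_causal_y)")
        if min(self.n_causal_x, self.n_causal_y, self.n_shared, self.n_causal_vol,
               self.n_pleiotropic_vol, self.n_signal_genes) < 0:
            raise ValidationError("counts must be nonnegative")
        n_y_spec = self.n_causal_y - self.n_shared
        needed = self.n_causal_x + n_y_spec + self.n_causal_vol
        if needed > self.n_snps:
            raise ValidationError(
                f"causal sets need {needed} variants but n_snps={self.n_snps}"
            )
        a, b, c = self.mediation_params
        if a * a > self.h2_y + 1e-12:
            raise ValidationError("mediation a-path variance a^2 exceeds h2_y")
        if a != 0.0 and n_y_spec < 1:
            raise ValidationError("mediation SNP requires a diet-y-specific variant")
        resid_var = 1.0 - (b * b + c * c + 2.0 * a * b * c)
        if resid_var <= 0.0:
            raise ValidationError(
                "mediation paths imply negative mediator-outcome residual variance"
            )
        reserve = 1 if a != 0.0 else 0
        if self.n_pleiotropic_vol > max(n_y_spec - reserve, 0):
            raise ValidationError(
                "n_pleiotropic_vol exceeds available diet-y-specific variants"
            )
        if not (-1.0 <= self.expression_r <= 1.0):
            raise ValidationError("expression_r must be in [-1, 1]")
        if self.n_signal_genes > self.n_genes:
            raise ValidationError("n_signal_genes exceeds n_genes")
        if self.region_effect_pattern is not None:
            pat = np.asarray(self.region_effect_pattern, float)
            if pat.shape != (self.n_regions,):
                raise ValidationError("region_effect_pattern length != n_regions")
            if not np.all(np.isfinite(pat)):
                raise ValidationError("region_effect_pattern has non-finite entries")
            self.region_effect_pattern = pat
        # variance bookkeeping for the volume model (checked here so an
        # inconsistent h2/noise specification fails before any simulation)
        d, q = self.causal_beta_xy, self.h2_vol
        if d * d + q >= 1.0:
            raise ValidationError(
                "causal_beta_xy^2 + h2_vol >= 1 implies negative volume noise variance"
            )

    def to_dict(self) -> dict:
        out = asdict(self)
        if out["region_effect_pattern"] is not None:
            out["region_effect_pattern"] = [float(v) for v in out["region_effect_pattern"]]
        out["maf_range"] = list(self.maf_range)
        out["region_baseline_range"] = list(self.region_baseline_range)
        out["mediation_params"] = list(self.mediation_params)
        return out


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the record of every generating parameter."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    volumes: RegionalVolumeMatrix
    expression: ExpressionMatrix
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.genotypes.n_samples
        if not (len(self.phenotypes) == n == len(self.volumes.sample_ids)):
            raise ValidationError("row counts disagree across cohort tables")

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Serialize every table as TSV and the truth record as YAML."""
        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": out / "genotypes.tsv",
            "variants": out / "variants.tsv",
            "phenotypes": out / "phenotypes.tsv",
            "volumes": out / "volumes.tsv",
            "expression": out / "expression.tsv",
            "truth": out / "truth.yaml",
        }
        _io.write_genotype_tsv(self.genotypes, paths["genotypes"], paths["variants"])
        _io.write_phenotype_tsv(self.phenotypes, paths["phenotypes"])
        _io.write_table(self.volumes.data.reset_index(), paths["volumes"])
        _io.write_table(
            self.expression.data.reset_index(), paths["expression"]
        )
        _io.write_yaml(self.truth, paths["truth"])
        return paths


def _validate_mafs(mafs: np.ndarray) -> np.ndarray:
    mafs = np.asarray(mafs, float)
    if not np.all(np.isfinite(mafs)):
        raise ValidationError("non-finite minor allele frequency")
    if np.any(mafs <= 0.0) or np.any(mafs >= 1.0):
        raise ValidationError("minor allele frequencies must lie in (0, 1)")
    return mafs


def simulate_genotypes(
    n: int,
    m: int,
    mafs: np.ndarray,
    seed: int,
    ld_rho: float = 0.0,
    ld_block_size: int = 1,
) -> GenotypeMatrix:
    """Draw an n x m dosage matrix under Hardy–Weinberg equilibrium.

    Each dosage is the sum of two independent allele draws per individual.
    With ``ld_rho > 0`` and ``ld_block_size > 1`` the allele draws within
    consecutive variant blocks share an AR(1) latent Gaussian, producing
    local correlation while preserving per-variant HWE margins.
    """
    if n < 1 or m < 1:
        raise ValidationError("n and m must be >= 1")
    mafs = _validate_mafs(np.broadcast_to(np.asarray(mafs, float), (m,)))
    rng = np.random.default_rng(seed)
    if ld_rho == 0.0 or ld_block_size <= 1:
        # two independent allele draws per individual (HWE by construction)
        maf32 = mafs.astype(np.float32)
        dosages = (rng.random((n, m), dtype=np.float32) < maf32).astype(np.int8)
        dosages += rng.random((n, m), dtype=np.float32) < maf32
    else:
        if not (0.0 <= ld_rho < 1.0):
            raise ValidationError("ld_rho must be in [0, 1)")
        thresh = stats.norm.ppf(mafs)
        dosages = np.zeros((n, m), dtype=np.int8)
        for _copy in range(2):
            latent = rng.standard_normal((n, m))
            for j in range(1, m):
                if j % ld_block_size != 0:
                    latent[:, j] = (
                        ld_rho * latent[:, j - 1]
                        + np.sqrt(1.0 - ld_rho**2) * latent[:, j]
                    )
            dosages += (latent < thresh).astype(np.int8)
    alleles = rng.integers(0, 4, size=(m, 2))
    alleles[:, 1] = (alleles[:, 0] + 1 + alleles[:, 1] % 3) % 4
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp_{j:06d}" for j in range(m)],
            "chrom": "1",
            "pos": 1 + 5000 * np.arange(m),
            "effect_allele": _BASES[alleles[:, 0]],
            "other_allele": _BASES[alleles[:, 1]],
        }
    )
    sample_ids = pd.Index([f"ind_{i:06d}" for i in range(n)], name="sample_id")
    return GenotypeMatrix(sample_ids, variants, dosages)


def _standardize_columns(D: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Standardize dosage columns by their theoretical HWE mean and SD."""
    sd = np.sqrt(2.0 * mafs * (1.0 - mafs))
    return (D - 2.0 * mafs) / sd


def _default_pattern(n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Lobe-structured loading pattern: 8 contiguous blocks with shared means."""
    n_lobes = min(8, n_regions)
    lobe_of = np.minimum(np.arange(n_regions) * n_lobes // n_regions, n_lobes - 1)
    lobe_means = rng.normal(1.0, 0.4, size=n_lobes)
    return lobe_means[lobe_of] + rng.normal(0.0, 0.25, size=n_regions)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort (genotypes, phenotypes, volumes, expression).

    See the module docstring for the generative model; the returned
    ``truth`` record carries every derived quantity needed by recovery
    tests, including the per-variant effect maps, the standardized causal
    effect of diet y on total volume, and the true proportion mediated.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(6)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in child]
    (s_geno, s_effects, s_phen, s_vol, s_expr, s_cov) = child_seeds

    rng_eff = np.random.default_rng(s_effects)
    rng_phen = np.random.default_rng(s_phen)
    rng_vol = np.random.default_rng(s_vol)
    rng_expr = np.random.default_rng(s_expr)
    rng_cov = np.random.default_rng(s_cov)

    n, m = cfg.n_individuals, cfg.n_snps
    mafs = np.random.default_rng(s_geno).uniform(*cfg.maf_range, size=m)
    genotypes = simulate_genotypes(
        n, m, mafs, seed=s_geno + 1, ld_rho=cfg.ld_rho, ld_block_size=cfg.ld_block_size
    )

    # --- causal variant index layout -------------------------------------
    n_y_spec = cfg.n_causal_y - cfg.n_shared
    idx_shared = np.arange(cfg.n_shared)
    idx_x_spec = np.arange(cfg.n_shared, cfg.n_causal_x)
    idx_y_spec = np.arange(cfg.n_causal_x, cfg.n_causal_x + n_y_spec)
    idx_vol = np.arange(
        cfg.n_causal_x + n_y_spec, cfg.n_causal_x + n_y_spec + cfg.n_causal_vol
    )
    a_path, b_path, c_prime = cfg.mediation_params
    med_idx = int(idx_y_spec[0]) if (a_path != 0.0 and n_y_spec > 0) else None
    pleio_pool = idx_y_spec[1:] if med_idx is not None else idx_y_spec
    idx_pleio = pleio_pool[: cfg.n_pleiotropic_vol]

    # --- standardized per-variant effects --------------------------------
    beta_x = np.zeros(m)
    beta_y = np.zeros(m)
    v_shared = rng_eff.standard_normal(cfg.n_shared)
    w_x = rng_eff.standard_normal(len(idx_x_spec))
    w_y = rng_eff.standard_normal(len(idx_y_spec))
    if cfg.h2_x > 0.0 and cfg.n_causal_x > 0:
        denom = float(v_shared @ v_shared + w_x @ w_x)
        alpha_x = np.sqrt(cfg.h2_x / denom) if denom > 0 else 0.0
        beta_x[idx_shared] = -alpha_x * v_shared
        beta_x[idx_x_spec] = alpha_x * w_x
    if cfg.h2_y > 0.0 and cfg.n_causal_y > 0:
        w_y_eff = w_y.copy()
        if med_idx is not None:
            w_y_eff[0] = 0.0
        denom = float(v_shared @ v_shared + w_y_eff @ w_y_eff)
        budget = cfg.h2_y - (a_path**2 if med_idx is not None else 0.0)
        alpha_y = np.sqrt(budget / denom) if denom > 0 and budget > 0 else 0.0
        beta_y[idx_shared] = alpha_y * v_shared
        beta_y[idx_y_spec] = alpha_y * w_y_eff
        if med_idx is not None:
            beta_y[med_idx] = a_path

    # direct polygenic volume score u (unit variance), with pleiotropic
    # contamination from diet-y causal variants
    beta_u = np.zeros(m)
    if cfg.h2_vol > 0.0 and (cfg.n_causal_vol > 0 or len(idx_pleio) > 0):
        raw_vol = rng_eff.standard_normal(cfg.n_causal_vol)
        raw_pleio = rng_eff.standard_normal(len(idx_pleio))
        norm = np.sqrt(float(raw_vol @ raw_vol + raw_pleio @ raw_pleio))
        beta_u[idx_vol] = raw_vol / norm
        beta_u[idx_pleio] = raw_pleio / norm
    rho_uy = float(beta_u @ beta_y)  # corr(diet_y genetic leak, u)

    # --- covariates -------------------------------------------------------
    age = rng_cov.normal(_AGE_MEAN, _AGE_SD, size=n)
    sex = np.where(rng_cov.random(n) < _P_FEMALE, "F", "M")
    site_labels = np.array(list(_SITE_PROBS))
    site = rng_cov.choice(site_labels, size=n, p=list(_SITE_PROBS.values()))
    age_c = age - _AGE_MEAN
    male = (sex == "M").astype(float)
    site_b = (site == "site_B").astype(float)
    diet_cov = _DIET_AGE_EFF * age_c + _DIET_SEX_EFF * male + _DIET_SITE_EFF * site_b

    # --- diets ------------------------------------------------------------
    causal_cols = np.unique(
        np.concatenate([idx_shared, idx_x_spec, idx_y_spec, idx_vol])
    ).astype(int)
    Z = _standardize_columns(
        genotypes.dosages[:, causal_cols].astype(np.float64), mafs[causal_cols]
    )
    g_x = Z @ beta_x[causal_cols]
    g_y = Z @ beta_y[causal_cols]
    u = Z @ beta_u[causal_cols]
    diet_x = g_x + rng_phen.standard_normal(n) * np.sqrt(1.0 - cfg.h2_x) + diet_cov
    diet_y = g_y + rng_phen.standard_normal(n) * np.sqrt(1.0 - cfg.h2_y) + diet_cov

    # --- mediator traits (SNP -> diet_y -> trait chains) ------------------
    if med_idx is not None:
        g_med = Z[:, int(np.searchsorted(causal_cols, med_idx))]
    else:
        g_med = Z[:, 0] if Z.shape[1] else np.zeros(n)
    resid_sd = np.sqrt(1.0 - (b_path**2 + c_prime**2 + 2 * a_path * b_path * c_prime))
    bmi = b_path * diet_y + c_prime * g_med + rng_phen.standard_normal(n) * resid_sd
    l_var = 1.0 - (
        _LIFESTYLE_B**2 + _LIFESTYLE_CPRIME**2
        + 2 * a_path * _LIFESTYLE_B * _LIFESTYLE_CPRIME
    )
    alcohol = (
        _LIFESTYLE_B * diet_y
        + _LIFESTYLE_CPRIME * g_med
        + rng_phen.standard_normal(n) * np.sqrt(l_var)
    )
    denom_pm = a_path * b_path + c_prime
    true_pm = (a_path * b_path / denom_pm) if denom_pm != 0.0 else float("nan")

    # --- regional volumes -------------------------------------------------
    R = cfg.n_regions
    pattern = (
        cfg.region_effect_pattern
        if cfg.region_effect_pattern is not None
        else _default_pattern(R, rng_vol)
    )
    L = float(np.sum(pattern))
    if cfg.causal_beta_xy != 0.0 and abs(L) < 1e-9:
        raise ValidationError(
            "region_effect_pattern sums to ~0; total-volume causal effect undefined"
        )
    d, q = cfg.causal_beta_xy, cfg.h2_vol
    sigma_tot2 = R * cfg.region_noise_sd**2
    var_denom = 1.0 - d * d - q - 2.0 * d * np.sqrt(q) * rho_uy
    if var_denom <= 0.0:
        raise ValidationError(
            "volume variance components exceed total (implied negative noise)"
        )
    V_tot = sigma_tot2 / var_denom  # covariate-adjusted TGMV variance
    sd_tot = np.sqrt(V_tot)
    beta_raw = d * sd_tot / L if d != 0.0 else 0.0  # volume units per SD intake
    u_load = np.sqrt(q * V_tot) / R  # uniform per-region direct-genetic loading
    baseline = rng_vol.uniform(*cfg.region_baseline_range, size=R)
    noise = rng_vol.standard_normal((n, R)) * cfg.region_noise_sd
    vols = (
        baseline
        + np.outer(beta_raw * diet_y, pattern)
        + u_load * u[:, None]
        + (_VOL_AGE_EFF * age_c + _VOL_SEX_EFF * male + _VOL_SITE_EFF * site_b)[:, None]
        + noise
    )
    region_labels = [f"region_{r + 1:03d}" for r in range(R)]
    volumes = RegionalVolumeMatrix(
        pd.DataFrame(np.clip(vols, 0.0, None), index=genotypes.sample_ids,
                     columns=region_labels)
    )

    # --- expression -------------------------------------------------------
    pat_z = (pattern - pattern.mean()) / pattern.std()
    r_e = cfg.expression_r
    expr = rng_expr.standard_normal((cfg.n_genes, R))
    for gi in range(cfg.n_signal_genes):
        noise_g = expr[gi]
        noise_z = (noise_g - noise_g.mean()) / noise_g.std()
        expr[gi] = r_e * pat_z + np.sqrt(1.0 - r_e**2) * noise_z
    gene_ids = [f"gene_{g + 1:04d}" for g in range(cfg.n_genes)]
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                     columns=region_labels)
    )

    if cfg.round_diets:
        diet_x = np.round(diet_x * 2.66 + 4.85)  # bowls/week scale
        diet_y = np.round(diet_y * 1.92 + 2.07)  # cups/day scale

    phen = pd.DataFrame(
        {
            "cereal_intake": diet_x,
            "coffee_intake": diet_y,
            "bmi": bmi,
            "alcohol_freq": alcohol,
            "mediation_snp": g_med,
            "age": age,
            "sex": sex,
            "site": site,
        },
        index=genotypes.sample_ids,
    )
    phenotypes = PhenotypeTable(phen, categorical=frozenset({"sex", "site"}))

    vid = genotypes.variants["variant_id"]
    truth = {
        "config": cfg.to_dict(),
        "child_seeds": child_seeds,
        "beta_x": {str(vid[j]): float(beta_x[j]) for j in np.flatnonzero(beta_x)},
        "beta_y": {str(vid[j]): float(beta_y[j]) for j in np.flatnonzero(beta_y)},
        "beta_vol_direct": {
            str(vid[j]): float(beta_u[j]) for j in np.flatnonzero(beta_u)
        },
        "pleiotropic_vol_variants": [str(vid[j]) for j in idx_pleio],
        "mediation_variant": str(vid[med_idx]) if med_idx is not None else None,
        "true_pm": float(true_pm) if np.isfinite(true_pm) else None,
        "pm_defined": bool(denom_pm != 0.0),
        "standardized_effect_xy": float(d),
        "volume_slope_per_sd_intake": float(beta_raw),
        "tgmv_sd": float(sd_tot),
        "rho_diet_vol_genetic": rho_uy,
        "region_effect_pattern": [float(x) for x in pattern],
        "signal_genes": gene_ids[: cfg.n_signal_genes],
        "causal_direction": "coffee_intake->total_gmv",
    }
    return SyntheticCohort(genotypes, phenotypes, volumes, expression, truth)


def simulate_mediation_triple(
    a: float,
    b: float,
    c_prime: float,
    n: int,
    seed: int,
    maf: float = 0.3,
) -> pd.DataFrame:
    """Simulate one standardized SNP -> mediator -> outcome chain.

    ``m = a*g + e1`` and ``y = b*m + c'*g + e2`` with residuals scaled so
    every variable has unit variance; ``g`` is a standardized HWE dosage.
    The true proportion mediated ``ab / (ab + c')`` is recorded in
    ``df.attrs["true_pm"]`` (NaN, with ``attrs["pm_defined"] = False``,
    when ``ab + c' = 0``).
    """
    if n < 10:
        raise ValidationError("n must be >= 10")
    for name, val in (("a", a), ("b", b), ("c_prime", c_prime)):
        if not np.isfinite(val):
            raise ValidationError(f"path {name} is not finite")
    if a * a >= 1.0:
        raise ValidationError("a^2 must be < 1")
    y_resid_var = 1.0 - (b * b + c_prime * c_prime + 2 * a * b * c_prime)
    if y_resid_var <= 0.0:
        raise ValidationError("paths imply negative outcome residual variance")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, maf, size=n)
    g = (dosage - 2 * maf) / np.sqrt(2 * maf * (1 - maf))
    m_var = np.sqrt(1.0 - a * a)
    m = a * g + rng.standard_normal(n) * m_var
    y = b * m + c_prime * g + rng.standard_normal(n) * np.sqrt(y_resid_var)
    df = pd.DataFrame(
        {"g": g, "m": m, "y": y},
        index=pd.Index([f"ind_{i:06d}" for i in range(n)], name="sample_id"),
    )
    denom = a * b + c_prime
    df.attrs["pm_defined"] = bool(denom != 0.0)
    df.attrs["true_pm"] = float(a * b / denom) if denom != 0.0 else float("nan")
    df.attrs["paths"] = {"a": a, "b": b, "c_prime": c_prime}
    return df
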