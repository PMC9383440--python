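"""Covariate-adjusted linear association scans and multiplicity diagnostics.

Two model classes follow the fit/results idiom:

* :class:`GwasScan` — per-variant OLS of a trait on effect-allele dosage plus
  covariates; :meth:`GwasScan.fit` returns a :class:`GwasResult` with per
  variant beta, SE, t, two-sided p, and the genomic inflation factor in its
  summary.
* :class:`RegionalAssociation` — one OLS per atlas region (region volume ~
  trait + covariates); its result is an :class:`AssociationPattern`, the
  signed-t spatial signature that pattern-similarity analyses operate on.

Conventions: missing dosages are mean-imputed per variant before OLS (the
standard PRS/GWAS convention); phenotype/covariate missingness is handled by
complete-case removal per analysis; two-sided p-values throughout the scan;
categorical covariates expand to first-level-dropped indicator contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import design_matrix, qr_basis, residualize, scan_outcomes, scan_predictors
from .containers import GenotypeMatrix, PhenotypeTable, RegionalVolumeMatrix
from .exceptions import EmptyResultError, ValidationError

#: median of the chi-square(1) distribution, the null expectation of the
#: median GWAS test statistic
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...

#: conventional genome-wide significance level
GENOME_WIDE_ALPHA = 5e-8


def adjust_covariates(
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    categorical: frozenset = frozenset(),
) -> tuple[np.ndarray, np.ndarray]:
    """Residualize a response on an intercept plus covariate columns.

    Rows with any missing value are removed first; returns ``(residuals,
    kept_mask)`` where the residuals are orthogonal (to numerical tolerance)
    to every covariate column and to the intercept.
    """
    y = pd.Series(np.asarray(y, float))
    covariates = covariates.reset_index(drop=True)
    keep = y.notna().to_numpy() & covariates.notna().all(axis=1).to_numpy()
    X, _ = design_matrix(covariates.loc[keep], list(covariates.columns), categorical)
    Q = qr_basis(X)
    resid = residualize(y.to_numpy()[keep], Q)
    return resid, keep


@dataclass
class GwasResult:
    """Per-variant association statistics for one trait."""

    table: pd.DataFrame  # variant_id chrom pos alleles beta se t p n_used
    trait: str
    covariates: tuple[str, ...]
    n_used: int

    def __post_init__(self) -> None:
        p = self.table["p"]
        if bool(((p <= 0) | (p > 1)).any()):
            raise ValidationError("p-values outside (0, 1]")
        se = self.table["se"]
        if bool((se[se.notna()] <= 0).any()):
            raise ValidationError("nonpositive standard errors")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def lambda_gc(self) -> float:
        return genomic_inflation(self)["lambda_gc"]

    def significant(self, alpha: float = GENOME_WIDE_ALPHA) -> pd.DataFrame:
        """Variants passing the (by default genome-wide) significance level."""
        return self.table[self.table["p"] <= alpha]

    def p_lookup(self) -> pd.Series:
        return self.table.set_index("variant_id")["p"]

    def summary(self) -> str:
        info = genomic_inflation(self)
        n_sig = int((self.table["p"] <= GENOME_WIDE_ALPHA).sum())
        lines = [
            f"GWAS scan of {self.trait!r} (n={self.n_used}, "
            f"m={self.n_variants} variants)",
            f"covariates: {', '.join(self.covariates) or 'none'}",
            f"genome-wide significant (p<=5e-08): {n_sig}",
            f"lambda_GC = {info['lambda_gc']:.3f} "
            f"(median chi2 {info['median_chi2']:.4f} over {info['n_tests']} tests)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from . import io as _io

        _io.write_table(self.table, path)

    def plot_manhattan(self, ax=None):
        from .plots import manhattan

        return manhattan(self, ax=ax)

    def plot_qq(self, ax=None):
        from .plots import qq_plot

        return qq_plot(self, ax=ax)


class GwasScan:
    """Genome-wide linear association scan (model object).

    OLS of ``trait ~ dosage_j + intercept + covariates`` for every variant
    ``j``, with two-sided p-values from the t distribution at the correct
    residual degrees of freedom.  Monomorphic variants are flagged and their
    statistics set missing, never fabricated.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotypes: PhenotypeTable,
        trait: str,
        covariates: tuple[str, ...] | list[str] = (),
        dtype=np.float64,
    ) -> None:
        self.genotypes = genotypes
        self.phenotypes = phenotypes
        self.trait = trait
        self.covariates = tuple(covariates)
        self.dtype = dtype
        if not genotypes.sample_ids.equals(phenotypes.sample_ids):
            if set(genotypes.sample_ids) != set(phenotypes.sample_ids):
                raise ValidationError("genotype and phenotype samples do not match")

    def fit(self) -> GwasResult:
        G, P = self.genotypes, self.phenotypes
        cols = [self.trait, *self.covariates]
        keep_ids = P.complete_cases(cols)
        phen = P.data.loc[G.sample_ids]
        keep = phen.index.isin(keep_ids)
        phen = phen.loc[keep]
        D = G.imputed_dosages(dtype=self.dtype)
        if not keep.all():
            D = D[keep]
        y = phen[self.trait].to_numpy(float)
        X, _ = design_matrix(phen, self.covariates, P.categorical)
        Q = qr_basis(X)
        beta, se, t, p, _df = scan_predictors(y, D, Q, overwrite_d=True)
        table = G.variants.copy()
        table["beta"] = beta
        table["se"] = se
        table["t"] = t
        table["p"] = p
        table["n_used"] = int(keep.sum())
        table["monomorphic"] = ~np.isfinite(beta)
        return GwasResult(table, self.trait, self.covariates, int(keep.sum()))


def gwas_scan(
    G: GenotypeMatrix,
    trait: str,
    covariates,
    P: PhenotypeTable,
) -> GwasResult:
    """Convenience wrapper: ``GwasScan(G, P, trait, covariates).fit()``."""
    return GwasScan(G, P, trait, covariates).fit()


def genomic_inflation(res: GwasResult) -> dict:
    """Genomic inflation factor: median chi-square over its null median.

    Uses the large-n convention chi2 = t**2; returns the factor together
    with the median statistic and the number of non-missing tests.
    """
    t = res.table["t"].to_numpy(float)
    chi2 = t[np.isfinite(t)] ** 2
    if chi2.size == 0:
        raise EmptyResultError("no non-missing tests for genomic inflation")
    med = float(np.median(chi2))
    return {
        "lambda_gc": med / CHI2_MEDIAN_1DF,
        "median_chi2": med,
        "n_tests": int(chi2.size),
    }


@dataclass
class AssociationPattern:
    """Per-region signed association signature of one phenotype.

    The pattern vector is the signed t-statistic of the trait term from one
    OLS per region; t is scale-free, which matters because regions have very
    different volume scales.  (A standardized-beta variant is available via
    ``statistic="std_beta"`` on :class:`RegionalAssociation`.)
    """

    phenotype: str
    region_labels: list[str]
    table: pd.DataFrame  # region beta se t p
    n_used: int
    statistic: str = "t"

    def __post_init__(self) -> None:
        if len(self.table) != len(self.region_labels):
            raise ValidationError("pattern length != region count")

    @property
    def vector(self) -> np.ndarray:
        """The pattern itself (one signed entry per atlas region)."""
        return self.table[self.statistic].to_numpy(float)

    def summary(self) -> str:
        v = self.vector
        ok = np.isfinite(v)
        return (
            f"GMV-association pattern of {self.phenotype!r} over "
            f"{len(self.region_labels)} regions (n={self.n_used}); "
            f"{int((~ok).sum())} flagged region(s); "
            f"mean {self.statistic} = {np.nanmean(v):.3f}"
        )

    def to_tsv(self, path) -> None:
        from . import io as _io

        _io.write_table(self.table, path)


class RegionalAssociation:
    """Region-wise association model: volume_r ~ trait + covariates."""

    def __init__(
        self,
        volumes: RegionalVolumeMatrix,
        phenotypes: PhenotypeTable,
        trait: str,
        covariates=(),
        statistic: str = "t",
    ) -> None:
        if statistic not in ("t", "std_beta"):
            raise ValidationError("statistic must be 't' or 'std_beta'")
        self.volumes = volumes
        self.phenotypes = phenotypes
        self.trait = trait
        self.covariates = tuple(covariates)
        self.statistic = statistic

    def fit(self) -> AssociationPattern:
        V, P = self.volumes, self.phenotypes
        cols = [self.trait, *self.covariates]
        keep_ids = P.complete_cases(cols)
        common = V.sample_ids.intersection(keep_ids)
        if len(common) == 0:
            raise EmptyResultError("no complete cases shared by volumes/phenotypes")
        Vm = V.data.loc[common].to_numpy(float)
        phen = P.data.loc[common]
        x = phen[self.trait].to_numpy(float)
        X, _ = design_matrix(phen, self.covariates, P.categorical)
        Q = qr_basis(X)
        beta, se, t, p, _df = scan_outcomes(Vm, x, Q)
        table = pd.DataFrame(
            {"region": V.region_labels, "beta": beta, "se": se, "t": t, "p": p}
        )
        if self.statistic == "std_beta":
            sd_x = np.std(x, ddof=1)
            sd_v = np.nanstd(Vm, axis=0, ddof=1)
            table["std_beta"] = beta * sd_x / np.where(sd_v > 0, sd_v, np.nan)
        return AssociationPattern(
            self.trait, V.region_labels, table, len(common), self.statistic
        )


def gmv_association_pattern(
    V: RegionalVolumeMatrix,
    trait: str,
    covariates,
    P: PhenotypeTable,
) -> AssociationPattern:
    """Convenience wrapper: ``RegionalAssociation(V, P, trait, cov).fit()``."""
    return RegionalAssociation(V, P, trait, covariates).fit()


def bonferroni_threshold(alpha: float, k1: int, k2: int = 1) -> float:
    """Two-factor Bonferroni screen, e.g. 0.05 / 166 regions / 17 diets."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must be in (0, 1)")
    if k1 < 1 or k2 < 1:
        raise ValidationError("counts must be >= 1")
    return alpha / (k1 * k2)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with NaN passthrough."""
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if ok.sum():
        _, q, _, _ = multipletests(p[ok], method="fdr_bh")
        out[ok] = q
    return out
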