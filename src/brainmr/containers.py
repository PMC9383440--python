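"""In-memory data containers.

Thin, validating wrappers around pandas/numpy objects:

* :class:`GenotypeMatrix` — individuals x variants dosages plus variant
  metadata; the substrate for GWAS scans, clumping, and PRS scoring.
* :class:`PhenotypeTable` — named numeric traits and typed covariates.
* :class:`RegionalVolumeMatrix` — per-region gray-matter volumes over a
  labeled atlas (166 regions by default); total volume is the row sum.
* :class:`ExpressionMatrix` — gene x region expression on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]


@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant metadata.

    Parameters
    ----------
    sample_ids : sequence of unique sample identifiers (length n).
    variants : DataFrame with columns ``variant_id, chrom, pos,
        effect_allele, other_allele``; positions are 1-based (VCF convention)
        and nondecreasing within chromosome.
    dosages : (n, m) array of effect-allele dosages in [0, 2]; fractional
        values (imputed data) and NaN (missing) are allowed.
    """

    sample_ids: pd.Index
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = pd.Index(self.sample_ids, name="sample_id")
        if self.sample_ids.has_duplicates:
            raise ValidationError("duplicate sample_ids in GenotypeMatrix")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValidationError(f"variant table missing columns: {missing_cols}")
        if self.variants["variant_id"].duplicated().any():
            dups = self.variants.loc[
                self.variants["variant_id"].duplicated(), "variant_id"
            ]
            raise ValidationError(f"duplicate variant ids: {list(dups[:5])} ...")
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bool(np.any(bad & ~np.isnan(self.dosages))):
            raise ValidationError("dosages outside [0, 2]")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValidationError("positions not nondecreasing within chromosome")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> pd.Index:
        return pd.Index(self.variants["variant_id"])

    def imputed_dosages(self, dtype=np.float64) -> np.ndarray:
        """Dosages with per-variant mean imputation of missing calls."""
        D = self.dosages.astype(dtype, copy=True)
        if np.issubdtype(self.dosages.dtype, np.floating) and np.isnan(D).any():
            means = np.nanmean(D, axis=0)
            means = np.where(np.isfinite(means), means, 0.0)
            idx = np.where(np.isnan(D))
            D[idx] = means[idx[1]]
        return D

    def allele_frequencies(self) -> np.ndarray:
        """Empirical effect-allele frequencies (missing calls ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class PhenotypeTable:
    """Sample-indexed traits and covariates.

    ``categorical`` names the covariates to expand as indicator contrasts;
    all other columns are treated as numeric.
    """

    data: pd.DataFrame
    categorical: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.data.index.name != "sample_id":
            if "sample_id" in self.data.columns:
                self.data = self.data.set_index("sample_id")
            else:
                self.data = self.data.rename_axis("sample_id")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample_ids in PhenotypeTable")
        self.categorical = frozenset(self.categorical)
        for cov in self.categorical:
            if cov not in self.data.columns:
                raise ValidationError(f"categorical covariate {cov!r} not in table")
            if self.data[cov].dropna().nunique() < 2:
                raise ValidationError(
                    f"categorical covariate {cov!r} has <2 observed levels"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise ValidationError(f"column {name!r} not in phenotype table")
        return self.data[name]

    def complete_cases(self, columns) -> pd.Index:
        """Sample ids with no missing value in any of ``columns``."""
        sub = self.data[list(columns)]
        return self.data.index[sub.notna().all(axis=1)]


@dataclass
class RegionalVolumeMatrix:
    """Per-region gray-matter volumes over a labeled atlas."""

    data: pd.DataFrame  # samples x regions

    def __post_init__(self) -> None:
        if self.data.index.name != "sample_id":
            if "sample_id" in self.data.columns:
                self.data = self.data.set_index("sample_id")
            else:
                self.data = self.data.rename_axis("sample_id")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample_ids in RegionalVolumeMatrix")
        vals = self.data.to_numpy(float)
        if bool(np.any(vals[np.isfinite(vals)] < 0)):
            raise ValidationError("regional volumes must be nonnegative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def region_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def total(self) -> pd.Series:
        """Total gray-matter volume: exact row sum over regions."""
        return self.data.sum(axis=1).rename("total_gmv")


@dataclass
class ExpressionMatrix:
    """Gene-by-region expression on a common normalized scale."""

    data: pd.DataFrame  # genes x regions

    def __post_init__(self) -> None:
        self.data = self.data.rename_axis("gene_id")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate gene ids in ExpressionMatrix")
        enough = self.data.notna().sum(axis=1) >= 3
        if not bool(enough.all()):
            bad = list(self.data.index[~enough][:5])
            raise ValidationError(f"genes with <3 non-missing regions: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def region_labels(self) -> list[str]:
        return list(self.data.columns)

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.data.index:
            raise ValidationError(f"gene {gene_id!r} not in expression matrix")
        return self.data.loc[gene_id]
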