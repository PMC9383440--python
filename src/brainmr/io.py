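"""File I/O: TSV dialects, a minimal VCF boundary, and YAML records.

Everything tabular is tab-separated text with a header row and ``NA`` for
missing values — an auditable format for a statistics pipeline.  VCF is
accepted only at the genotype boundary (GT fields to dosages, multiallelic
records rejected) and written only in a minimal GT-only dialect.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import VARIANT_COLUMNS, GenotypeMatrix, PhenotypeTable
from .exceptions import ValidationError

NA_REP = "NA"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with header; missing values become ``NA``."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def read_table(
    path: str | Path,
    schema: dict[str, type] | None = None,
    required: list[str] | None = None,
) -> pd.DataFrame:
    """Read a TSV with header, optionally enforcing a column schema.

    ``schema`` maps column names to dtypes applied after parsing; columns
    named in ``required`` (or in ``schema``) that are absent raise a
    :class:`ValidationError` listing the offenders.  Malformed rows are
    reported with their line numbers; floats parse with round-trip
    precision so that write∘read is the identity.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            na_values=[NA_REP],
            keep_default_na=True,
            float_precision="round_trip",
            on_bad_lines="error",
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed row ({exc})") from exc
    need = list(required or []) + list(schema or {})
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if schema:
        for col, dtype in schema.items():
            try:
                df[col] = df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: column {col!r} not coercible to {dtype}: {exc}"
                ) from exc
    return df


def write_yaml(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(obj), fh, sort_keys=False)


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# genotype dialects


def write_genotype_tsv(
    G: GenotypeMatrix, dosage_path: str | Path, variants_path: str | Path | None = None
) -> None:
    """Dosage dialect: ``sample_id`` then one column per variant id.

    Variant metadata (chromosome, position, alleles) goes to the optional
    sidecar ``variants_path``.
    """
    df = pd.DataFrame(
        G.dosages, index=G.sample_ids, columns=G.variants["variant_id"]
    ).reset_index()
    write_table(df, dosage_path)
    if variants_path is not None:
        write_table(G.variants[VARIANT_COLUMNS], variants_path)


def read_genotype_tsv(
    dosage_path: str | Path, variants_path: str | Path | None = None
) -> GenotypeMatrix:
    df = read_table(dosage_path, required=["sample_id"])
    sample_ids = pd.Index(df["sample_id"].astype(str), name="sample_id")
    dosages = df.drop(columns="sample_id").to_numpy(float)
    variant_ids = [c for c in df.columns if c != "sample_id"]
    if variants_path is not None:
        variants = read_table(variants_path, required=VARIANT_COLUMNS)
        variants = variants.set_index("variant_id").loc[variant_ids].reset_index()
        variants["chrom"] = variants["chrom"].astype(str)
    else:
        variants = pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chrom": "1",
                "pos": 1 + 5000 * np.arange(len(variant_ids)),
                "effect_allele": "A",
                "other_allele": "G",
            }
        )
    return GenotypeMatrix(sample_ids, variants, dosages)


def write_phenotype_tsv(P: PhenotypeTable, path: str | Path) -> None:
    write_table(P.data.reset_index(), path)


def read_phenotype_tsv(path: str | Path, categorical=()) -> PhenotypeTable:
    df = read_table(path, required=["sample_id"])
    df["sample_id"] = df["sample_id"].astype(str)
    return PhenotypeTable(df.set_index("sample_id"), frozenset(categorical))


def read_volume_tsv(path: str | Path):
    from .containers import RegionalVolumeMatrix

    df = read_table(path, required=["sample_id"])
    df["sample_id"] = df["sample_id"].astype(str)
    return RegionalVolumeMatrix(df.set_index("sample_id"))


def read_expression_tsv(path: str | Path):
    from .containers import ExpressionMatrix

    df = read_table(path, required=["gene_id"])
    return ExpressionMatrix(df.set_index("gene_id"))


# ---------------------------------------------------------------------------
# minimal VCF boundary


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from VCF via cyvcf2 (GT to effect-allele dosage).

    The ALT allele is the effect allele.  Multiallelic records are
    rejected; missing GT becomes NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = pd.Index(vcf.samples, name="sample_id")
    rows, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"multiallelic record at {var.CHROM}:{var.POS} rejected"
            )
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(dos)
        rows.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "effect_allele": var.ALT[0],
                "other_allele": var.REF,
            }
        )
    if not rows:
        raise ValidationError(f"{path}: no variant records")
    return GenotypeMatrix(sample_ids, pd.DataFrame(rows), np.column_stack(cols))


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (integer dosages rounded to genotypes)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        D = G.dosages
        for j, var in enumerate(G.variants.itertuples()):
            calls = [
                "./." if np.isnan(d) else gt_of[int(round(float(d)))]
                for d in D[:, j]
            ]
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.variant_id}\t{var.other_allele}\t"
                f"{var.effect_allele}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
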