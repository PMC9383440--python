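"""Polygenic score construction and scoring.

Native reimplementation of the PRSice-style procedure: greedy LD clumping of
a discovery GWAS, p-value-threshold variant selection, and allele-harmonized
weighted-dosage scoring.  Default clumping parameters (r2_max=0.1,
window_kb=250, p_index=5e-8) are conventional and configurable; they are
recorded in the model provenance because the exact values a given study used
are rarely printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import GwasResult
from .containers import GenotypeMatrix
from .exceptions import AlleleMismatchError, ValidationError


@dataclass
class PrsModel:
    """A set of (variant, effect allele, weight) entries plus provenance.

    Weights are discovery-GWAS betas on the stated effect allele.  After
    pleiotropy pruning, ``pruned_against`` records each (confound phenotype,
    removal threshold) pass that produced this "valid-PRS".
    """

    entries: pd.DataFrame  # variant_id, effect_allele, weight [, p]
    p_threshold: float
    provenance: str = ""
    pruned_against: list = field(default_factory=list)

    def __post_init__(self) -> None:
        need = {"variant_id", "effect_allele", "weight"}
        if not need <= set(self.entries.columns):
            raise ValidationError(f"PrsModel entries need columns {sorted(need)}")
        if self.entries["variant_id"].duplicated().any():
            raise ValidationError("duplicate variant ids in PrsModel")
        if not np.all(np.isfinite(self.entries["weight"])):
            raise ValidationError("non-finite PRS weights")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValidationError("p_threshold must be in (0, 1]")
        self.entries = self.entries.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.entries)

    @property
    def is_empty(self) -> bool:
        return len(self.entries) == 0

    def to_tsv(self, path, sidecar: str | Path | None = None) -> None:
        from . import io as _io

        _io.write_table(self.entries, path)
        if sidecar is not None:
            _io.write_yaml(
                {
                    "p_threshold": float(self.p_threshold),
                    "provenance": self.provenance,
                    "pruned_against": [
                        [str(c), float(t)] for c, t in self.pruned_against
                    ],
                },
                sidecar,
            )

    @classmethod
    def from_tsv(cls, path, sidecar: str | Path | None = None) -> "PrsModel":
        from . import io as _io

        entries = _io.read_table(path)
        meta = {"p_threshold": 1.0, "provenance": "", "pruned_against": []}
        if sidecar is not None:
            meta.update(_io.read_yaml(sidecar))
        return cls(
            entries,
            p_threshold=float(meta["p_threshold"]),
            provenance=str(meta["provenance"]),
            pruned_against=[(c, float(t)) for c, t in meta["pruned_against"]],
        )


def clump(
    res: "GwasResult",
    G: GenotypeMatrix,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
    p_index: float = 5e-8,
) -> list[str]:
    """Greedy selection of independent lead variants.

    Repeatedly takes the smallest-p unclaimed variant with ``p <= p_index``
    as a lead and claims every variant within ``window_kb`` whose squared
    Pearson dosage correlation with it is at least ``r2_max``.  Ties on p
    break toward the smaller genomic coordinate (determinism).  Undefined
    r-squared (monomorphic partner) is treated as 0.
    """
    tab = res.table
    idx_of = {v: i for i, v in enumerate(tab["variant_id"])}
    cand = tab[np.isfinite(tab["p"]) & (tab["p"] <= p_index)]
    if cand.empty:
        return []
    cand = cand.sort_values(["p", "chrom", "pos"], kind="mergesort")
    D = G.imputed_dosages()
    Dc = D - D.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", Dc, Dc))
    claimed: set[str] = set()
    leads: list[str] = []
    window = window_kb * 1000.0
    by_chrom = {c: g for c, g in tab.groupby("chrom", sort=False)}
    for row in cand.itertuples():
        if row.variant_id in claimed:
            continue
        leads.append(row.variant_id)
        claimed.add(row.variant_id)
        near = by_chrom[row.chrom]
        near = near[(near["pos"] - row.pos).abs() <= window]
        j = idx_of[row.variant_id]
        for other in near.itertuples():
            if other.variant_id in claimed:
                continue
            k = idx_of[other.variant_id]
            denom = norms[j] * norms[k]
            r2 = 0.0 if denom == 0 else (float(Dc[:, j] @ Dc[:, k]) / denom) ** 2
            if r2 >= r2_max:
                claimed.add(other.variant_id)
    return leads


def build_prs(
    res: "GwasResult",
    p_threshold: float = 0.05,
    leads_only: bool = False,
    leads: list[str] | None = None,
    provenance: str = "",
) -> PrsModel:
    """Threshold-select discovery variants into a PRS model.

    Entries are the variants with ``p <= p_threshold`` (restricted to
    ``leads`` when ``leads_only``); the weight is the discovery beta on the
    stated effect allele.  An empty selection yields an empty (flagged)
    model rather than an error.
    """
    if res.n_variants == 0:
        raise ValidationError("empty GWAS result")
    tab = res.table
    sel = np.isfinite(tab["p"].to_numpy()) & (tab["p"].to_numpy() <= p_threshold)
    if leads_only:
        if leads is None:
            raise ValidationError("leads_only=True requires a leads list")
        sel &= tab["variant_id"].isin(leads).to_numpy()
    entries = tab.loc[sel, ["variant_id", "effect_allele", "beta", "p"]].rename(
        columns={"beta": "weight"}
    )
    return PrsModel(
        entries.reset_index(drop=True),
        p_threshold=p_threshold,
        provenance=provenance or f"gwas:{res.trait}",
    )


def score(model: PrsModel, G: GenotypeMatrix) -> pd.Series:
    """Per-sample weighted dosage sum after allele harmonization.

    Model variants stored on the panel's other allele are flipped (weight
    applied to ``2 - dosage``); variants matching neither orientation raise
    :class:`AlleleMismatchError` listing the offenders.  Missing dosages are
    mean-imputed.  An empty model scores everyone 0.
    """
    if model.is_empty:
        return pd.Series(0.0, index=G.sample_ids, name="prs")
    panel = G.variants.set_index("variant_id")
    missing = [v for v in model.entries["variant_id"] if v not in panel.index]
    if missing:
        raise AlleleMismatchError(missing)
    sub = panel.loc[model.entries["variant_id"]]
    same = (sub["effect_allele"].to_numpy() == model.entries["effect_allele"].to_numpy())
    flipped = (sub["other_allele"].to_numpy() == model.entries["effect_allele"].to_numpy())
    bad = ~(same | flipped)
    if bad.any():
        raise AlleleMismatchError(model.entries.loc[bad, "variant_id"].tolist())
    col = G.variant_index().get_indexer(model.entries["variant_id"])
    D = G.dosages[:, col].astype(float)
    if np.isnan(D).any():
        means = np.nanmean(D, axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        idx = np.where(np.isnan(D))
        D[idx] = means[idx[1]]
    w = model.entries["weight"].to_numpy(float)
    sign = np.where(same, 1.0, -1.0)
    offset = float(w[flipped].sum()) * 2.0
    values = D @ (w * sign) + offset
    return pd.Series(values, index=G.sample_ids, name="prs")
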