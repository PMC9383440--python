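"""Modified bidirectional Mendelian randomization with stepwise pleiotropy
removal.

The idea: a genetic variant's indirect effect on a downstream (dependent)
trait is always weaker than its direct effect on the upstream (independent)
trait, so by stepwise removing variants that cross-associate with the
*other* trait at progressively laxer p-value thresholds (0.05 to 0.50 in
steps of 0.05), the surviving "valid-PRS" retains only variants acting on
its own trait — a usable instrumental variable.  Because instruments for
both traits are built simultaneously, causality can be probed in both
directions, addressing reverse causation directly.

:class:`BidirectionalMR` is the model object; :meth:`BidirectionalMR.fit`
returns an :class:`MrReport` holding, per direction and per removal
threshold, the instrument size and the covariate-adjusted partial
correlations of the (valid-)PRS with exposure and outcome, with one-tailed
p-values.  The verdict rule and a fixed-effect IVW cross-check live here
too.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import design_matrix, one_tailed_p, partial_correlation, qr_basis
from .association import GwasResult
from .containers import GenotypeMatrix, PhenotypeTable
from .exceptions import EmptyResultError, ValidationError
from .prs import PrsModel, build_prs, score

DEFAULT_LADDER = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))

VERDICTS = ("X_causes_Y", "Y_causes_X", "bidirectional", "inconclusive")


def remove_pleiotropy(
    model: PrsModel, confound_gwas: GwasResult, t: float
) -> PrsModel:
    """Drop model variants cross-associated with the confound below p < t.

    Strict inequality: a variant with confound p exactly equal to ``t`` is
    retained.  Variants absent from the confound GWAS are retained and
    counted in the returned model's provenance.  Larger ``t`` removes a
    superset of what smaller ``t`` removes (monotonicity).
    """
    if not (0.0 < t <= 1.0):
        raise ValidationError("removal threshold must be in (0, 1]")
    lookup = confound_gwas.p_lookup()
    p_conf = model.entries["variant_id"].map(lookup)
    uncovered = int((~model.entries["variant_id"].isin(lookup.index)).sum())
    keep = ~(p_conf < t)  # NaN (uncovered or monomorphic confound) -> keep
    entries = model.entries.loc[keep.to_numpy()].reset_index(drop=True)
    pruned = PrsModel(
        entries,
        p_threshold=model.p_threshold,
        provenance=model.provenance,
        pruned_against=[*model.pruned_against, (confound_gwas.trait, float(t))],
    )
    pruned.n_uncovered = uncovered
    return pruned


def ivw_estimate(beta_x, se_x, beta_y, se_y) -> dict:
    """Fixed-effect inverse-variance-weighted causal estimate.

    Weighted least squares of outcome effects on exposure effects through
    the origin, weights 1/se_y^2:

        beta = sum(bx*by/se_y^2) / sum(bx^2/se_y^2),
        SE   = sqrt(1 / sum(bx^2/se_y^2)),

    with a two-sided normal p-value.  ``se_x`` is accepted for interface
    completeness (first-order IVW ignores exposure-side noise).
    """
    bx = np.asarray(beta_x, float)
    by = np.asarray(beta_y, float)
    sy = np.asarray(se_y, float)
    if bx.size == 0:
        raise EmptyResultError("IVW needs at least one instrument")
    if np.any(sy <= 0):
        raise ValidationError("outcome standard errors must be positive")
    if np.all(bx == 0):
        raise ValidationError("all exposure effects are zero; IVW undefined")
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = beta / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return {"beta": beta, "se": se, "p": p, "n_instruments": int(bx.size)}


@dataclass
class MrReport:
    """Ladder-resolved bidirectional MR results.

    ``table`` has one raw-PRS row (``t`` = NaN) plus one row per removal
    threshold for each direction, with instrument size, the instrument-
    exposure partial correlation (validity check) and the instrument-outcome
    partial correlation, both with one-tailed p.  ``metadata`` records the
    covariates, the tail conventions, the caller's two-sample disjointness
    assertion, and sample hashes.
    """

    x: str
    y: str
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    alpha: float = 0.05
    min_frac: float = 1.0

    def __post_init__(self) -> None:
        ladder = self.table[self.table["t"].notna()]
        for direction, grp in ladder.groupby("direction"):
            counts = grp.sort_values("t")["n_variants"].to_numpy()
            if np.any(np.diff(counts) > 0):
                raise ValidationError(
                    f"retained-variant counts not nonincreasing in t ({direction})"
                )

    @property
    def verdict(self) -> str:
        return causal_verdict(self, self.alpha, self.min_frac)

    @property
    def verdict_lenient(self) -> str:
        """Weaker support tier: consistent sign with >=30% significant rows."""
        return causal_verdict(self, self.alpha, min_frac=0.3)

    def direction_rows(self, direction: str, ladder_only: bool = True) -> pd.DataFrame:
        rows = self.table[self.table["direction"] == direction]
        return rows[rows["t"].notna()] if ladder_only else rows

    def summary(self) -> str:
        lines = [
            f"Bidirectional MR: {self.x} <-> {self.y}",
            f"strict verdict (all rows significant):    {self.verdict}",
            f"lenient verdict (>=30% rows significant): {self.verdict_lenient}",
            "",
            self.table.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path, verdict_sidecar=None) -> None:
        from . import io as _io

        _io.write_table(self.table, path)
        if verdict_sidecar is not None:
            _io.write_yaml(
                {
                    "x": self.x,
                    "y": self.y,
                    "verdict": self.verdict,
                    "verdict_lenient": self.verdict_lenient,
                    "alpha": float(self.alpha),
                    "min_frac": float(self.min_frac),
                    "metadata": self.metadata,
                },
                verdict_sidecar,
            )

    def plot_ladder(self, ax=None):
        from .plots import mr_ladder

        return mr_ladder(self, ax=ax)


def causal_verdict(
    report: MrReport, alpha: float = 0.05, min_frac: float = 1.0
) -> str:
    """Verdict rule over the ladder.

    A direction is supported when (i) the instrument predicts its own
    exposure at ``p < alpha`` in every ladder row (instrument validity) and
    (ii) the instrument-outcome association is significant in at least
    ``min_frac`` of rows with a consistent sign across all rows.  Fewer
    than 3 usable rows in either direction forces ``inconclusive``.
    """

    def supported(direction: str) -> bool | None:
        rows = report.direction_rows(direction)
        rows = rows[(rows["n_variants"] > 0) & rows["p_exposure"].notna()]
        if len(rows) < 3:
            return None
        valid = bool((rows["p_exposure"] < alpha).all())
        sig_frac = float((rows["p_outcome"] < alpha).mean())
        signs = np.sign(rows["r_outcome"].to_numpy(float))
        consistent = bool(np.all(signs == signs[0]) and signs[0] != 0)
        return valid and consistent and sig_frac >= min_frac

    fwd = supported("X->Y")
    rev = supported("Y->X")
    if fwd is None or rev is None:
        return "inconclusive"
    if fwd and rev:
        return "bidirectional"
    if fwd:
        return "X_causes_Y"
    if rev:
        return "Y_causes_X"
    return "inconclusive"


class BidirectionalMR:
    """Model object for the stepwise bidirectional MR analysis.

    Parameters
    ----------
    target_genotypes, target_phenotypes : the target sample, which must be
        disjoint from both discovery GWAS samples (caller-asserted via
        ``discovery_disjoint``; the report stamps sample hashes so the
        assertion is auditable, but the module cannot verify disjointness
        from IDs it never sees).
    x_gwas, y_gwas : discovery association scans for the two traits; PRS
        weights and cross-association p-values both come from these.
    x, y : trait names in the target phenotype table.
    covariates : adjusted out of every partial correlation.
    ladder : removal thresholds (defaults 0.05..0.50 step 0.05).
    p_threshold : PRS inclusion threshold (0.05, the PRSice-style default).
    """

    def __init__(
        self,
        target_genotypes: GenotypeMatrix,
        target_phenotypes: PhenotypeTable,
        x: str,
        y: str,
        x_gwas: GwasResult,
        y_gwas: GwasResult,
        covariates=(),
        ladder=DEFAULT_LADDER,
        p_threshold: float = 0.05,
        alpha: float = 0.05,
        min_frac: float = 1.0,
        discovery_disjoint: bool = True,
    ) -> None:
        if not discovery_disjoint:
            raise ValidationError(
                "two-sample MR requires discovery samples disjoint from the target"
            )
        self.G = target_genotypes
        self.P = target_phenotypes
        self.x, self.y = x, y
        self.x_gwas, self.y_gwas = x_gwas, y_gwas
        self.covariates = tuple(covariates)
        self.ladder = tuple(float(t) for t in ladder)
        if any(not (0 < t <= 1) for t in self.ladder):
            raise ValidationError("ladder thresholds must lie in (0, 1]")
        self.p_threshold = p_threshold
        self.alpha = alpha
        self.min_frac = min_frac

    def _prepare(self):
        cols = [self.x, self.y, *self.covariates]
        keep_ids = self.P.complete_cases(cols)
        phen = self.P.data.loc[self.G.sample_ids]
        keep = phen.index.isin(keep_ids)
        phen = phen.loc[keep]
        X, _ = design_matrix(phen, self.covariates, self.P.categorical)
        return phen, keep, qr_basis(X)

    def fit(self) -> MrReport:
        phen, keep, Q = self._prepare()
        xv = phen[self.x].to_numpy(float)
        yv = phen[self.y].to_numpy(float)
        # observational association fixes the one-tailed outcome direction
        r_obs, _, _ = partial_correlation(xv, yv, Q)
        obs_sign = 1 if r_obs >= 0 else -1

        prs_x = build_prs(self.x_gwas, self.p_threshold, provenance=f"gwas:{self.x}")
        prs_y = build_prs(self.y_gwas, self.p_threshold, provenance=f"gwas:{self.y}")

        rows = []
        for direction, model, confound, expo, outc in (
            ("X->Y", prs_x, self.y_gwas, xv, yv),
            ("Y->X", prs_y, self.x_gwas, yv, xv),
        ):
            rows.append(self._row(direction, None, model, expo, outc, keep, Q, obs_sign))
            for t in self.ladder:
                pruned = remove_pleiotropy(model, confound, t)
                rows.append(
                    self._row(direction, t, pruned, expo, outc, keep, Q, obs_sign)
                )
        table = pd.DataFrame(rows)
        meta = {
            "covariates": list(self.covariates),
            "p_threshold": float(self.p_threshold),
            "ladder": list(self.ladder),
            "outcome_tail_sign": obs_sign,
            "observational_r": float(r_obs),
            "discovery_disjoint_asserted": True,
            "target_sample_hash": _sample_hash(phen.index),
            "clumping": "none (LD-free panel assumed); configure via prs.clump",
        }
        return MrReport(
            self.x, self.y, table, meta, alpha=self.alpha, min_frac=self.min_frac
        )

    def _row(self, direction, t, model, expo, outc, keep, Q, obs_sign) -> dict:
        base = {
            "direction": direction,
            "t": np.nan if t is None else float(t),
            "n_variants": model.n_variants,
        }
        if model.is_empty:
            return {
                **base,
                "r_exposure": np.nan,
                "p_exposure": np.nan,
                "r_outcome": np.nan,
                "p_outcome": np.nan,
            }
        s = score(model, self.G).to_numpy(float)[keep]
        r_e, t_e, df = partial_correlation(s, expo, Q)
        r_o, t_o, _ = partial_correlation(s, outc, Q)
        return {
            **base,
            "r_exposure": r_e,
            "p_exposure": one_tailed_p(t_e, df, +1),
            "r_outcome": r_o,
            "p_outcome": one_tailed_p(t_o, df, obs_sign),
        }


def stepwise_mr(
    G_target: GenotypeMatrix,
    P_target: PhenotypeTable,
    x_gwas: GwasResult,
    y_gwas: GwasResult,
    x: str,
    y: str,
    covariates=(),
    **kwargs,
) -> MrReport:
    """Convenience wrapper over :class:`BidirectionalMR`."""
    return BidirectionalMR(
        G_target, P_target, x, y, x_gwas, y_gwas, covariates, **kwargs
    ).fit()


def _sample_hash(index: pd.Index) -> str:
    h = hashlib.sha256()
    for s in index.astype(str):
        h.update(s.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]
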