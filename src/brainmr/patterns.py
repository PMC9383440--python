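"""Brain-wide pattern similarity with an ID-shuffling permutation null.

The observed statistic is the Pearson correlation between two spatial
signatures over atlas regions: either two GMV-association patterns, or one
GMV-association pattern and a gene's regional expression profile.  The null
distribution permutes which individual each imaging row belongs to — one
shared permutation of the volume matrix per iteration — severing every
volume–phenotype link while preserving the covariance of volumes across
regions (so oversampled/correlated regions cannot inflate false positives)
and the trait–covariate structure.  Patterns are recomputed from scratch on
each permuted dataset and the permutation p-value is (k+1)/(n_perm+1),
where k counts null draws at least as extreme as the observed correlation
under the declared tail (two-tailed by default; one-tailed for
replication-style tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import design_matrix, qr_basis, residualize
from .association import AssociationPattern, bh_fdr
from .containers import ExpressionMatrix, PhenotypeTable, RegionalVolumeMatrix
from .exceptions import ValidationError

_MIN_PERM = 100
_MIN_REGIONS = 3


def pattern_correlation(a, b) -> float:
    """Pearson correlation between two region-aligned pattern vectors.

    Accepts :class:`AssociationPattern` objects or plain vectors; uses
    pairwise-complete regions and requires at least 3 of them with
    nonzero variance on both sides.
    """
    va = a.vector if isinstance(a, AssociationPattern) else np.asarray(a, float)
    vb = b.vector if isinstance(b, AssociationPattern) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValidationError("pattern vectors have different lengths")
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < _MIN_REGIONS:
        raise ValidationError("fewer than 3 pairwise-complete regions")
    x, y = va[ok] - va[ok].mean(), vb[ok] - vb[ok].mean()
    nx, ny = float(x @ x), float(y @ y)
    if nx == 0.0 or ny == 0.0:
        raise ValidationError("zero-variance pattern")
    return float(np.clip((x @ y) / np.sqrt(nx * ny), -1.0, 1.0))


@dataclass
class PatternSimilarityResult:
    """Observed pattern correlation plus its permutation null summary."""

    pair: str
    r: float
    n_perm: int
    k: int  # null draws at least as extreme as observed
    tail: str  # "two" | "one"
    n_regions: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r <= 1.0):
            raise ValidationError("r outside [-1, 1]")
        if self.k > self.n_perm:
            raise ValidationError("exceedance count exceeds permutation count")

    @property
    def p_perm(self) -> float:
        return (self.k + 1) / (self.n_perm + 1)

    @property
    def p_display(self) -> str:
        """Paper-style reporting: a '<' bound when no null draw exceeds r."""
        if self.k == 0:
            return f"<{1.0 / self.n_perm:.0E}"
        return f"{self.p_perm:.4G}"

    def summary(self) -> str:
        return (
            f"pattern similarity {self.pair}: r = {self.r:.4f} over "
            f"{self.n_regions} regions; P_perm = {self.p_display} "
            f"({self.tail}-tailed, {self.n_perm} permutations)"
        )


class PatternSimilarity:
    """Permutation-tested pattern similarity over one volume matrix.

    Model object bound to (volumes, phenotypes, covariates).  The expensive
    per-iteration quantity — the permuted-data association pattern — is
    produced by a closed-form residual scan so that screening thousands of
    genes can share a single permutation stream.
    """

    def __init__(
        self,
        volumes: RegionalVolumeMatrix,
        phenotypes: PhenotypeTable,
        covariates=(),
    ) -> None:
        self.volumes = volumes
        self.phenotypes = phenotypes
        self.covariates = tuple(covariates)

    # -- internals --------------------------------------------------------

    def _prepare(self, traits: list[str]):
        P, V = self.phenotypes, self.volumes
        keep_ids = P.complete_cases([*traits, *self.covariates])
        common = V.sample_ids.intersection(keep_ids)
        if len(common) < 10:
            raise ValidationError("fewer than 10 complete cases")
        phen = P.data.loc[common]
        Vm = V.data.loc[common].to_numpy(float)
        X, _ = design_matrix(phen, self.covariates, P.categorical)
        Q = qr_basis(X)
        xs = [residualize(phen[t].to_numpy(float), Q) for t in traits]
        return Vm, Q, xs, len(common)

    @staticmethod
    def _t_pattern(Vm, Q, x_r, vv, df) -> np.ndarray:
        """Signed t-statistics of the trait term, one per region.

        ``Vm`` may be row-permuted relative to (Q, x_r); in that case the
        caller permutes ``x_r`` and ``Q`` instead, which yields identical
        statistics because the permutation is orthogonal.
        """
        sxx = float(x_r @ x_r)
        QtV = Q.T @ Vm
        vMv = vv - np.einsum("ij,ij->j", QtV, QtV)
        sxy = x_r @ Vm
        beta = sxy / sxx
        sse = np.clip(vMv - beta * sxy, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / np.sqrt(sse / df / sxx)
        const = vMv <= 1e-10 * np.maximum(vv, 1.0)
        t[const] = np.nan
        return t

    def _null_stream(self, Vm, Q, xs, n_perm, seed):
        """Yield the observed patterns, then one tuple of null patterns per
        permutation (one shared shuffle of the volume rows per iteration)."""
        n, _R = Vm.shape
        df = n - Q.shape[1] - 1
        if df <= 0:
            raise ValidationError("not enough observations for the scan")
        vv = np.einsum("ij,ij->j", Vm, Vm)
        yield tuple(self._t_pattern(Vm, Q, x, vv, df) for x in xs)
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Qp = Q[perm]
            yield tuple(
                self._t_pattern(Vm, Qp, x[perm], vv, df) for x in xs
            )

    @staticmethod
    def _exceed(r_obs: float, r_null: np.ndarray, tail: str, sign: int = 1) -> int:
        if tail == "two":
            return int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-15))
        return int(np.sum(sign * r_null >= sign * r_obs - 1e-15))

    # -- public operations -------------------------------------------------

    def pair_test(
        self,
        trait_a: str,
        trait_b: str,
        n_perm: int = 10_000,
        seed: int = 0,
        tail: str = "two",
        expected_sign: int = 1,
    ) -> PatternSimilarityResult:
        """Similarity of two traits' GMV-association patterns.

        Each iteration applies one shared row permutation of the volume
        matrix and regenerates BOTH patterns, preserving the cross-trait
        null dependence induced by the shared volumes.
        """
        _check_perm_args(n_perm, tail)
        Vm, Q, xs, _n = self._prepare([trait_a, trait_b])
        stream = self._null_stream(Vm, Q, xs, n_perm, seed)
        pa, pb = next(stream)
        r_obs = pattern_correlation(pa, pb)
        null = np.fromiter(
            (pattern_correlation(na, nb) for na, nb in stream), float, count=n_perm
        )
        k = self._exceed(r_obs, null, tail, expected_sign)
        return PatternSimilarityResult(
            f"{trait_a}~{trait_b}", r_obs, n_perm, k, tail, Vm.shape[1]
        )

    def expression_test(
        self,
        expression: ExpressionMatrix,
        gene: str,
        trait: str,
        n_perm: int = 10_000,
        seed: int = 0,
        tail: str = "two",
        expected_sign: int = 1,
    ) -> PatternSimilarityResult:
        """Similarity of a gene's regional expression with a GMV pattern.

        The expression vector is fixed; only the GMV-association pattern is
        regenerated under each shuffled-ID iteration.
        """
        _check_perm_args(n_perm, tail)
        evec, cols = self._align_expression(expression, [gene])
        Vm, Q, xs, _n = self._prepare([trait])
        Vm = Vm[:, cols]
        stream = self._null_stream(Vm, Q, xs, n_perm, seed)
        (pat,) = next(stream)
        r_obs = pattern_correlation(evec[0], pat)
        null = np.fromiter(
            (pattern_correlation(evec[0], p[0]) for p in stream), float, count=n_perm
        )
        k = self._exceed(r_obs, null, tail, expected_sign)
        return PatternSimilarityResult(
            f"{gene}~{trait}", r_obs, n_perm, k, tail, len(cols)
        )

    def screen(
        self,
        expression: ExpressionMatrix,
        trait: str,
        n_perm: int = 1_000,
        seed: int = 0,
        alpha_fdr: float = 0.05,
        tail: str = "two",
    ) -> pd.DataFrame:
        """Transcriptome-wide screen sharing one permutation stream.

        The null patterns are gene-independent, so they are computed once
        per iteration and correlated against every gene — identical
        p-values to the naive per-gene loop at a fraction of the cost.
        Returns a table (gene, region_count, r, p_perm, q) with BH q-values
        across genes and a ``significant`` flag at ``alpha_fdr``.
        """
        _check_perm_args(n_perm, tail)
        if len(expression.gene_ids) == 0:
            raise ValidationError("empty expression matrix")
        E, cols = self._align_expression(expression, list(expression.gene_ids))
        Vm, Q, xs, _n = self._prepare([trait])
        Vm = Vm[:, cols]
        stream = self._null_stream(Vm, Q, xs, n_perm, seed)
        (pat,) = next(stream)
        r_obs = _corr_rows(E, pat)
        exceed = np.zeros(len(r_obs), dtype=int)
        for (null_pat,) in stream:
            r_null = _corr_rows(E, null_pat)
            if tail == "two":
                exceed += np.abs(r_null) >= np.abs(r_obs) - 1e-15
            else:
                exceed += r_null >= r_obs - 1e-15
        p_perm = (exceed + 1) / (n_perm + 1)
        q = bh_fdr(p_perm)
        out = pd.DataFrame(
            {
                "gene": list(expression.gene_ids),
                "region_count": len(cols),
                "r": r_obs,
                "p_perm": p_perm,
                "q": q,
            }
        )
        out["significant"] = out["q"] < alpha_fdr
        return out

    def _align_expression(self, expression: ExpressionMatrix, genes: list[str]):
        """Intersect expression regions with the atlas by exact label match."""
        atlas = self.volumes.region_labels
        shared = [r for r in atlas if r in set(expression.region_labels)]
        if len(shared) < _MIN_REGIONS:
            raise ValidationError("fewer than 3 regions shared with the atlas")
        cols = [atlas.index(r) for r in shared]
        E = expression.data.loc[genes, shared].to_numpy(float)
        return E, cols


def _check_perm_args(n_perm: int, tail: str) -> None:
    if n_perm < _MIN_PERM:
        raise ValidationError(
            f"n_perm must be >= {_MIN_PERM} (unstable null below that)"
        )
    if tail not in ("two", "one"):
        raise ValidationError("tail must be 'two' or 'one'")


def _corr_rows(E: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Pearson correlation of each expression row with one pattern vector,
    NaN regions excluded pairwise (vectorized over the common mask)."""
    ok = np.isfinite(pattern)
    pat = pattern[ok]
    Em = E[:, ok]
    mask = np.isfinite(Em)
    if mask.all():
        p = pat - pat.mean()
        X = Em - Em.mean(axis=1, keepdims=True)
        num = X @ p
        den = np.sqrt(np.einsum("ij,ij->i", X, X) * float(p @ p))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.clip(num / den, -1.0, 1.0)
    out = np.empty(E.shape[0])
    for i in range(E.shape[0]):
        m = mask[i]
        if m.sum() < _MIN_REGIONS:
            out[i] = np.nan
            continue
        x = Em[i, m] - Em[i, m].mean()
        y = pat[m] - pat[m].mean()
        den = np.sqrt(float(x @ x) * float(y @ y))
        out[i] = np.clip(float(x @ y) / den, -1.0, 1.0) if den > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# functional wrappers


def permutation_pattern_test(
    V: RegionalVolumeMatrix,
    trait_a: str,
    trait_b: str,
    covariates,
    P: PhenotypeTable,
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str = "two",
) -> PatternSimilarityResult:
    """Functional form of :meth:`PatternSimilarity.pair_test`."""
    return PatternSimilarity(V, P, covariates).pair_test(
        trait_a, trait_b, n_perm=n_perm, seed=seed, tail=tail
    )


def expression_pattern_test(
    E: ExpressionMatrix,
    gene: str,
    pattern_source: tuple,
    n_perm: int = 10_000,
    seed: int = 0,
    tail: str = "two",
) -> PatternSimilarityResult:
    """Functional form of :meth:`PatternSimilarity.expression_test`.

    ``pattern_source`` is ``(V, trait, covariates, P)``.
    """
    V, trait, covariates, P = pattern_source
    return PatternSimilarity(V, P, covariates).expression_test(
        E, gene, trait, n_perm=n_perm, seed=seed, tail=tail
    )


def screen_genes(
    E: ExpressionMatrix,
    pattern_source: tuple,
    n_perm: int = 1_000,
    seed: int = 0,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Functional form of :meth:`PatternSimilarity.screen`."""
    V, trait, covariates, P = pattern_source
    return PatternSimilarity(V, P, covariates).screen(
        E, trait, n_perm=n_perm, seed=seed, alpha_fdr=alpha_fdr
    )


def two_stage_filter(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha_fdr: float = 0.05,
    alpha_rep: float = 0.05,
) -> pd.DataFrame:
    """Discovery/replication gene filter.

    Keeps genes with BH q < ``alpha_fdr`` in the discovery screen AND
    p_perm < ``alpha_rep`` with a sign-consistent correlation in the
    replication screen.
    """
    rep = replication.set_index("gene")
    disc = discovery.set_index("gene")
    common = disc.index.intersection(rep.index)
    d, r = disc.loc[common], rep.loc[common]
    keep = (
        (d["q"] < alpha_fdr)
        & (r["p_perm"] < alpha_rep)
        & (np.sign(d["r"]) == np.sign(r["r"]))
    )
    return d.loc[keep, ["r", "p_perm", "q"]].join(
        r.loc[keep, ["r", "p_perm"]], lsuffix="_discovery", rsuffix="_replication"
    ).reset_index()
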