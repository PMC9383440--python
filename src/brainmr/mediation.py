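"""Causal-steps mediation with bootstrap proportion-mediated.

The total effect tau comes from OLS ``y ~ x + covariates``; the direct
effect tau' and the b-path from ``y ~ x + m + covariates``; the a-path from
``m ~ x + covariates``.  The proportion mediated is PM = (tau - tau') / tau,
which in the linear case equals ab / (ab + c').  Its p-value is the doubled
chance of observing PM < 0 across bootstrap resamples of individuals
(1,000 by default), capped at 1 and reported as a "< 2/n_boot" bound when no
negative draw occurs.  Competing mediator models sharing an exposure are
compared by their excess PM (PM_A - PM_B) evaluated on paired resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import design_matrix, ols_fit
from .containers import PhenotypeTable
from .exceptions import ValidationError

_UNSTABLE_FRAC = 0.10  # undefined-PM draws above this flag the result
_NEG_PM_FRAC = 0.25  # sign-convention warning threshold
_TAU_TOL = 1e-12


@dataclass
class MediationResult:
    """Point estimates, Baron–Kenny criteria flags, and the bootstrap PM."""

    exposure: str
    mediator: str
    outcome: str
    tau: float
    tau_prime: float
    a_path: float
    b_path: float
    pm: float
    criteria: dict
    n: int
    pm_draws: np.ndarray | None = None
    p_boot: float | None = None
    p_is_bound: bool = False
    n_boot: int = 0
    n_undefined: int = 0
    unstable: bool = False
    negative_pm_warning: bool = False
    seed: int | None = None
    path_p: dict = field(default_factory=dict)

    @property
    def mediation_established(self) -> bool:
        """All four causal-steps criteria hold."""
        return all(self.criteria.values())

    @property
    def p_display(self) -> str:
        if self.p_boot is None:
            return "NA"
        if self.p_is_bound:
            return f"<{self.p_boot:.4G}"
        return f"{self.p_boot:.4G}"

    def summary(self) -> str:
        crit = ", ".join(f"{k}={'Y' if v else 'N'}" for k, v in self.criteria.items())
        lines = [
            f"mediation {self.exposure} -> {self.mediator} -> {self.outcome} "
            f"(n={self.n})",
            f"tau={self.tau:.4g}  tau'={self.tau_prime:.4g}  "
            f"a={self.a_path:.4g}  b={self.b_path:.4g}",
            f"PM = {self.pm:.4f} ({self.pm * 100:.2f}%)",
            f"criteria: {crit}",
        ]
        if self.n_boot:
            lines.append(
                f"bootstrap: P = {self.p_display} ({self.n_boot} draws, "
                f"{self.n_undefined} undefined"
                + (", UNSTABLE" if self.unstable else "")
                + ")"
            )
        return "\n".join(lines)


@dataclass
class ExcessPmResult:
    """Excess-PM comparison of two mediator models sharing an exposure."""

    mediator_a: str
    mediator_b: str
    pm_a: float
    pm_b: float
    excess: float
    excess_draws: np.ndarray
    p_boot: float
    p_is_bound: bool
    preferred: str  # mediator name or "undecided"
    n_boot: int
    n_undefined: int
    negative_pm_warning: bool = False

    def summary(self) -> str:
        return (
            f"excess PM ({self.mediator_a} vs {self.mediator_b}): "
            f"{self.excess * 100:.2f}% "
            f"(PM_A={self.pm_a * 100:.2f}%, PM_B={self.pm_b * 100:.2f}%), "
            f"P = {'<' if self.p_is_bound else ''}{self.p_boot:.4G}; "
            f"preferred mediator: {self.preferred}"
        )


class MediationModel:
    """Baron–Kenny mediation model bound to one phenotype table.

    ``fit()`` returns point estimates and the four criteria flags;
    ``fit_bootstrap()`` adds the resampled-individuals PM distribution and
    its doubled-tail p-value.  Covariates are refit inside every bootstrap
    draw (no hat-matrix reuse).
    """

    def __init__(
        self,
        phenotypes: PhenotypeTable | pd.DataFrame,
        exposure: str,
        mediator: str,
        outcome: str,
        covariates=(),
        alpha: float = 0.05,
    ) -> None:
        if isinstance(phenotypes, pd.DataFrame):
            phenotypes = PhenotypeTable(phenotypes)
        self.P = phenotypes
        self.exposure, self.mediator, self.outcome = exposure, mediator, outcome
        self.covariates = tuple(covariates)
        self.alpha = alpha
        cols = [exposure, mediator, outcome, *self.covariates]
        keep = self.P.complete_cases(cols)
        phen = self.P.data.loc[keep]
        self._x = phen[exposure].to_numpy(float)
        self._m = phen[mediator].to_numpy(float)
        self._y = phen[outcome].to_numpy(float)
        for name, v in (("exposure", self._x), ("mediator", self._m),
                        ("outcome", self._y)):
            if np.std(v) == 0.0:
                raise ValidationError(f"{name} has zero variance")
        r_xm = np.corrcoef(self._x, self._m)[0, 1]
        if abs(r_xm) > 0.999:
            raise ValidationError("mediator is collinear with the exposure (|r|>0.999)")
        C, _ = design_matrix(phen, self.covariates, self.P.categorical)
        self._C = C  # intercept-led covariate design
        self._n = len(phen)

    # -- core fits ---------------------------------------------------------

    @staticmethod
    def _paths(x, m, y, C) -> tuple[float, float, float, float, dict]:
        """(tau, tau_prime, a, b) plus two-sided path p-values."""
        from scipy import stats as _st

        def term_fit(resp, *terms):
            X = np.column_stack([*terms, C])
            beta, se, df = ols_fit(resp, X)
            t = beta / np.where(se > 0, se, np.nan)
            p = 2.0 * _st.t.sf(np.abs(t), df)
            return beta, p

        b_tot, p_tot = term_fit(y, x)
        b_dir, p_dir = term_fit(y, x, m)
        b_med, p_med = term_fit(m, x)
        paths_p = {
            "tau": float(p_tot[0]),
            "tau_prime": float(p_dir[0]),
            "b": float(p_dir[1]),
            "a": float(p_med[0]),
        }
        return float(b_tot[0]), float(b_dir[0]), float(b_med[0]), float(b_dir[1]), paths_p

    def fit(self) -> MediationResult:
        tau, tau_prime, a, b, path_p = self._paths(self._x, self._m, self._y, self._C)
        pm = (tau - tau_prime) / tau if abs(tau) > _TAU_TOL else float("nan")
        criteria = {
            "exposure_outcome": path_p["tau"] < self.alpha,
            "exposure_mediator": path_p["a"] < self.alpha,
            "mediator_outcome_given_exposure": path_p["b"] < self.alpha,
            "direct_smaller_than_total": abs(tau_prime) < abs(tau),
        }
        return MediationResult(
            self.exposure,
            self.mediator,
            self.outcome,
            tau=tau,
            tau_prime=tau_prime,
            a_path=a,
            b_path=b,
            pm=pm,
            criteria=criteria,
            n=self._n,
            path_p=path_p,
        )

    def _pm_for_draws(self, draws: np.ndarray) -> np.ndarray:
        """PM per bootstrap resample; NaN where tau is degenerate."""
        out = np.empty(len(draws))
        for i, idx in enumerate(draws):
            x, m, y, C = self._x[idx], self._m[idx], self._y[idx], self._C[idx]
            try:
                tau, tau_prime, _a, _b, _p = self._paths(x, m, y, C)
            except (ValidationError, np.linalg.LinAlgError):
                out[i] = np.nan
                continue
            out[i] = (tau - tau_prime) / tau if abs(tau) > _TAU_TOL else np.nan
        return out

    def fit_bootstrap(self, n_boot: int = 1000, seed: int = 0) -> MediationResult:
        if n_boot < 100:
            raise ValidationError("n_boot must be >= 100")
        res = self.fit()
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, self._n, size=(n_boot, self._n))
        pm_draws = self._pm_for_draws(draws)
        valid = pm_draws[np.isfinite(pm_draws)]
        n_undef = int(n_boot - valid.size)
        p, is_bound = _doubled_tail_p(valid)
        res.pm_draws = pm_draws
        res.p_boot = p
        res.p_is_bound = is_bound
        res.n_boot = n_boot
        res.n_undefined = n_undef
        res.unstable = n_undef > _UNSTABLE_FRAC * n_boot
        res.negative_pm_warning = (
            valid.size > 0 and float(np.mean(valid < 0)) > _NEG_PM_FRAC
        )
        res.seed = seed
        return res


def _doubled_tail_p(valid_draws: np.ndarray) -> tuple[float, bool]:
    """Doubled chance of a draw below zero; exact zeros count half (tie rule).

    A zero count is reported as the bound 2/n (the paper-style "<" result).
    """
    n = valid_draws.size
    if n == 0:
        return float("nan"), False
    neg = float(np.sum(valid_draws < 0)) + 0.5 * float(np.sum(valid_draws == 0))
    if neg == 0:
        return min(2.0 / n, 1.0), True
    return min(2.0 * neg / n, 1.0), False


# ---------------------------------------------------------------------------
# functional wrappers


def causal_steps(
    x: str, m: str, y: str, covariates, P: PhenotypeTable, alpha: float = 0.05
) -> MediationResult:
    """Point-estimate causal-steps mediation (no bootstrap)."""
    return MediationModel(P, x, m, y, covariates, alpha=alpha).fit()


def bootstrap_pm(
    x: str,
    m: str,
    y: str,
    covariates,
    P: PhenotypeTable,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Complete mediation analysis with the bootstrap PM distribution."""
    return MediationModel(P, x, m, y, covariates).fit_bootstrap(n_boot, seed)


def excess_pm(
    model_a: MediationModel,
    model_b: MediationModel,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.05,
) -> ExcessPmResult:
    """Compare two mediator models by their bootstrapped excess PM.

    Both models must share the exposure variable and the sample; the same
    resample is applied to both per draw (paired draws — independent
    resampling would inflate the excess variance).  The preferred mediator
    is declared only when the doubled-tail p falls below ``level``; a model
    whose tau degenerates in more than 10% of draws forces "undecided".
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if model_a.exposure != model_b.exposure:
        raise ValidationError("excess-PM models must share the exposure")
    if model_a._n != model_b._n or not np.array_equal(model_a._x, model_b._x):
        raise ValidationError("excess-PM models must share the sample")
    pm_a_hat = model_a.fit().pm
    pm_b_hat = model_b.fit().pm
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, model_a._n, size=(n_boot, model_a._n))
    pm_a = model_a._pm_for_draws(draws)
    pm_b = model_b._pm_for_draws(draws)
    ok = np.isfinite(pm_a) & np.isfinite(pm_b)
    n_undef = int(n_boot - ok.sum())
    excess_draws = pm_a[ok] - pm_b[ok]
    undef_a = int(np.sum(~np.isfinite(pm_a)))
    undef_b = int(np.sum(~np.isfinite(pm_b)))
    unstable = max(undef_a, undef_b) > _UNSTABLE_FRAC * n_boot
    if unstable or excess_draws.size == 0:
        p, is_bound = float("nan"), False
        preferred = "undecided"
    else:
        p, is_bound = _doubled_tail_p(excess_draws)
        p_rev, _ = _doubled_tail_p(-excess_draws)
        point = pm_a_hat - pm_b_hat
        if p < level and point > 0:
            preferred = model_a.mediator
        elif p_rev < level and point < 0:
            preferred = model_b.mediator
        else:
            preferred = "undecided"
    neg_warn = bool(
        np.mean(np.concatenate([pm_a[ok], pm_b[ok]]) < 0) > _NEG_PM_FRAC
    ) if ok.any() else False
    return ExcessPmResult(
        mediator_a=model_a.mediator,
        mediator_b=model_b.mediator,
        pm_a=pm_a_hat,
        pm_b=pm_b_hat,
        excess=pm_a_hat - pm_b_hat,
        excess_draws=excess_draws,
        p_boot=p,
        p_is_bound=is_bound,
        preferred=preferred,
        n_boot=n_boot,
        n_undefined=n_undef,
        negative_pm_warning=neg_warn,
    )
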