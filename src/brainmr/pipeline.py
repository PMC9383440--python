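"""End-to-end driver: simulate -> gwas -> prs -> mr -> patterns -> mediation.

A :class:`RunConfig` (strict YAML schema; unknown keys rejected) enables any
subset of the six stages.  Each stage writes its outputs under the run
directory and appends a manifest record (stage, output hashes, seed, wall
time); a stage whose upstream artifacts are missing fails with an error
naming the stage to run first.  Per-stage seeds are derived deterministically
from the master seed at config resolution, so an identical config yields
hash-identical outputs.

The discovery/target split used by the PRS and MR stages is the first/second
half of the simulated cohort — a stand-in for the study design of running
discovery GWAS in one batch and instrument association tests in an
independent batch.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io as _io
from .association import GwasScan, RegionalAssociation
from .containers import GenotypeMatrix, PhenotypeTable, RegionalVolumeMatrix
from .exceptions import BrainMrError, ValidationError
from .mediation import MediationModel, excess_pm
from .mr import BidirectionalMR
from .patterns import PatternSimilarity
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("brainmr")

STAGES = ("simulate", "gwas", "prs", "mr", "patterns", "mediation")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_Strict):
    enabled: bool = True
    config: dict = {}


class GwasStage(_Strict):
    enabled: bool = True
    traits: list[str] = ["cereal_intake", "coffee_intake", "total_gmv"]
    covariates: list[str] = ["age", "sex", "site"]


class PrsStage(_Strict):
    enabled: bool = True
    p_threshold: float = 0.05


class MrStage(_Strict):
    enabled: bool = True
    x: str = "coffee_intake"
    y: str = "total_gmv"
    ladder_start: float = 0.05
    ladder_stop: float = 0.50
    ladder_step: float = 0.05
    alpha: float = 0.05
    min_frac: float = 1.0


class PatternsStage(_Strict):
    enabled: bool = True
    trait_a: str = "cereal_intake"
    trait_b: str = "coffee_intake"
    n_perm: int = 1000
    screen_expression: bool = True


class MediationStage(_Strict):
    enabled: bool = True
    exposure: str = "mediation_snp"
    mediator: str = "coffee_intake"
    outcome: str = "bmi"
    n_boot: int = 1000
    compare_reversed: bool = True


class RunConfig(_Strict):
    """Full pipeline configuration; see module docstring."""

    out_dir: str = "brainmr_run"
    seed: int = 0
    log_level: str = "INFO"
    covariates: list[str] = ["age", "sex", "site"]
    simulate: SimulateStage = SimulateStage()
    gwas: GwasStage = GwasStage()
    prs: PrsStage = PrsStage()
    mr: MrStage = MrStage()
    patterns: PatternsStage = PatternsStage()
    mediation: MediationStage = MediationStage()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = _io.read_yaml(path) or {}
        return cls(**raw)

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        return {
            name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(STAGES, ss.spawn(len(STAGES)))
        }


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


class _Context:
    """In-memory artifacts passed between stages, with lazy reload from disk."""

    def __init__(self, out: Path):
        self.out = out
        self.cohort = None
        self.gwas: dict[str, object] = {}

    def require_cohort(self):
        if self.cohort is None:
            geno = self.out / "cohort" / "genotypes.tsv"
            if not geno.exists():
                raise ValidationError(
                    "missing cohort artifacts; run the 'simulate' stage first"
                )
            self.cohort = _load_cohort(self.out / "cohort")
        return self.cohort

    def require_gwas(self, trait: str):
        if trait not in self.gwas:
            raise ValidationError(
                f"missing GWAS result for {trait!r}; run the 'gwas' stage first"
            )
        return self.gwas[trait]


def _load_cohort(cdir: Path):
    from .simulate import SyntheticCohort

    G = _io.read_genotype_tsv(cdir / "genotypes.tsv", cdir / "variants.tsv")
    P = _io.read_phenotype_tsv(cdir / "phenotypes.tsv", categorical=("sex", "site"))
    V = _io.read_volume_tsv(cdir / "volumes.tsv")
    E = _io.read_expression_tsv(cdir / "expression.tsv")
    truth = _io.read_yaml(cdir / "truth.yaml")
    return SyntheticCohort(G, P, V, E, truth)


def _with_total_gmv(P: PhenotypeTable, V: RegionalVolumeMatrix) -> PhenotypeTable:
    data = P.data.copy()
    data["total_gmv"] = V.total
    return PhenotypeTable(data, P.categorical)


def _split(cohort):
    """Deterministic discovery/target halves of a cohort."""
    n = cohort.genotypes.n_samples
    half = n // 2
    return _subset(cohort, slice(0, half)), _subset(cohort, slice(half, n))


def _subset(cohort, sl):
    ids = cohort.genotypes.sample_ids[sl]
    G = GenotypeMatrix(
        ids, cohort.genotypes.variants.copy(), cohort.genotypes.dosages[sl]
    )
    P = PhenotypeTable(cohort.phenotypes.data.loc[ids], cohort.phenotypes.categorical)
    V = RegionalVolumeMatrix(cohort.volumes.data.loc[ids])
    from .simulate import SyntheticCohort

    return SyntheticCohort(G, P, V, cohort.expression, cohort.truth)


def run_pipeline(config: RunConfig) -> list[dict]:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    seeds = config.stage_seeds()
    ctx = _Context(out)
    manifest: list[dict] = []

    runners = {
        "simulate": _run_simulate,
        "gwas": _run_gwas,
        "prs": _run_prs,
        "mr": _run_mr,
        "patterns": _run_patterns,
        "mediation": _run_mediation,
    }
    try:
        for stage in STAGES:
            if not getattr(config, stage).enabled:
                continue
            t0 = time.perf_counter()
            log.info("stage %s starting (seed %d)", stage, seeds[stage])
            outputs = runners[stage](config, ctx, seeds[stage])
            rec = {
                "stage": stage,
                "seed": seeds[stage],
                "outputs": {str(p.name): _hash_file(p) for p in outputs},
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
            manifest.append(rec)
            log.info("stage %s done in %.2fs", stage, rec["wall_time_s"])
    finally:
        _io.write_yaml({"stages": manifest, "seed": config.seed}, out / "manifest.yaml")
        log.removeHandler(fh)
        fh.close()
    return manifest


def _run_simulate(config: RunConfig, ctx: _Context, seed: int) -> list[Path]:
    params = dict(config.simulate.config)
    params.setdefault("seed", seed)
    cohort = simulate_cohort(SimulationConfig(**params))
    ctx.cohort = cohort
    paths = cohort.write(ctx.out / "cohort")
    return list(paths.values())


def _run_gwas(config: RunConfig, ctx: _Context, seed: int) -> list[Path]:
    cohort = ctx.require_cohort()
    discovery, _target = _split(cohort)
    P = _with_total_gmv(discovery.phenotypes, discovery.volumes)
    outputs = []
    for trait in config.gwas.traits:
        res = GwasScan(
            discovery.genotypes, P, trait, tuple(config.gwas.covariates)
        ).fit()
        ctx.gwas[trait] = res
        path = ctx.out / f"gwas_{trait}.tsv"
        res.to_tsv(path)
        outputs.append(path)
    return outputs


def _run_prs(config: RunConfig, ctx: _Context, seed: int) -> list[Path]:
    from .prs import build_prs, score

    cohort = ctx.require_cohort()
    _discovery, target = _split(cohort)
    outputs = []
    scores = {}
    for trait in config.gwas.traits:
        res = ctx.require_gwas(trait)
        model = build_prs(res, config.prs.p_threshold, provenance=f"gwas:{trait}")
        path = ctx.out / f"prs_{trait}.tsv"
        model.to_tsv(path, sidecar=ctx.out / f"prs_{trait}.yaml")
        scores[f"prs_{trait}"] = score(model, target.genotypes)
        outputs += [path, ctx.out / f"prs_{trait}.yaml"]
    spath = ctx.out / "prs_scores.tsv"
    _io.write_table(pd.DataFrame(scores).reset_index(), spath)
    outputs.append(spath)
    return outputs


def _run_mr(config: RunConfig, ctx: _Context, seed: int) -> list[Path]:
    cohort = ctx.require_cohort()
    _discovery, target = _split(cohort)
    P = _with_total_gmv(target.phenotypes, target.volumes)
    c = config.mr
    ladder = np.round(
        np.arange(c.ladder_start, c.ladder_stop + c.ladder_step / 2, c.ladder_step), 6
    )
    report = BidirectionalMR(
        target.genotypes,
        P,
        c.x,
        c.y,
        ctx.require_gwas(c.x),
        ctx.require_gwas(c.y),
        covariates=tuple(config.covariates),
        ladder=ladder,
        p_threshold=config.prs.p_threshold,
        alpha=c.alpha,
        min_frac=c.min_frac,
    ).fit()
    tsv, side = ctx.out / "mr_report.tsv", ctx.out / "mr_verdict.yaml"
    report.to_tsv(tsv, verdict_sidecar=side)
    return [tsv, side]


def _run_patterns(config: RunConfig, ctx: _Context, seed: int) -> list[Path]:
    cohort = ctx.require_cohort()
    c = config.patterns
    model = PatternSimilarity(
        cohort.volumes, cohort.phenotypes, tuple(config.covariates)
    )
    pair = model.pair_test(c.trait_a, c.trait_b, n_perm=c.n_perm, seed=seed)
    outputs = []
    results = {
        "pair": pair.pair,
        "r": float(pair.r),
        "p_perm": float(pair.p_perm),
        "p_display": pair.p_display,
        "n_perm": pair.n_perm,
    }
    for trait in (c.trait_a, c.trait_b):
        pat = RegionalAssociation(
            cohort.volumes, cohort.phenotypes, trait, tuple(config.covariates)
        ).fit()
        path = ctx.out / f"pattern_{trait}.tsv"
        pat.to_tsv(path)
        outputs.append(path)
    if c.screen_expression:
        screen = model.screen(
            cohort.expression, c.trait_b, n_perm=c.n_perm, seed=seed + 1
        )
        spath = ctx.out / "expression_screen.tsv"
        _io.write_table(screen, spath)
        outputs.append(spath)
        results["n_significant_genes"] = int(screen["significant"].sum())
    ypath = ctx.out / "pattern_similarity.yaml"
    _io.write_yaml(results, ypath)
    outputs.append(ypath)
    return outputs


def _run_mediation(config: RunConfig, ctx: _Context, seed: int) -> list[Path]:
    cohort = ctx.require_cohort()
    c = config.mediation
    P = _with_total_gmv(cohort.phenotypes, cohort.volumes)
    covs = tuple(config.covariates)
    model = MediationModel(P, c.exposure, c.mediator, c.outcome, covs)
    res = model.fit_bootstrap(n_boot=c.n_boot, seed=seed)
    out = {
        "exposure": c.exposure,
        "mediator": c.mediator,
        "outcome": c.outcome,
        "tau": res.tau,
        "tau_prime": res.tau_prime,
        "a": res.a_path,
        "b": res.b_path,
        "pm": res.pm,
        "p_boot": res.p_boot,
        "p_display": res.p_display,
        "criteria": res.criteria,
        "n_boot": res.n_boot,
        "n_undefined": res.n_undefined,
        "seed": seed,
    }
    if c.compare_reversed:
        reversed_model = MediationModel(P, c.exposure, c.outcome, c.mediator, covs)
        cmp_res = excess_pm(model, reversed_model, n_boot=c.n_boot, seed=seed)
        out["excess_pm_vs_reversed"] = {
            "excess": cmp_res.excess,
            "p_boot": cmp_res.p_boot,
            "preferred": cmp_res.preferred,
        }
    path = ctx.out / "mediation.yaml"
    _io.write_yaml(out, path)
    return [path]
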