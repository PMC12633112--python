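"""End-to-end pipeline: simulate -> impute/QC -> FGWAS -> meta -> compare.

Configuration is a YAML file validated by pydantic models; every
stochastic stage derives its stream from the single top-level seed, so a
rerun with the same configuration reproduces all outputs bit-for-bit.  A
manifest records input hashes, seeds, versions and per-stage attrition
counts.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

import famgwas
from famgwas import io as fio
from famgwas.compare import compare_effects, series_from_sumstats
from famgwas.fgwas import run_fgwas
from famgwas.impute import mendelian_consistency_report
from famgwas.meta import cohort_from_sumstats, meta_analyze
from famgwas.simulate import (
    AssortativeMatingConfig,
    SimulationConfig,
    StratificationConfig,
    simulate_assortative_mating,
    simulate_random_mating,
)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


class StratModel(BaseModel):
    n_demes: int = 2
    fst_like_divergence: float = 0.1
    env_shift: float = 0.0


class AmModel(BaseModel):
    target_cross_mate_corr: float = 0.3
    n_generations: int = 20
    matching_trait: str = "dge_component"


class SimulateModel(BaseModel):
    n_families: int = 2000
    n_snps: int = 500
    maf_low: float = 0.05
    maf_high: float = 0.5
    h2_direct: float = 0.3
    ige_coefficient: float = 0.0
    strat: StratModel | None = None
    am: AmModel | None = None
    family_design: dict[str, float] = Field(
        default_factory=lambda: {"trio": 0.5, "sib_pair_no_parents": 0.3, "one_parent_duo": 0.2}
    )

    @field_validator("family_design")
    @classmethod
    def _sums_to_one(cls, v):
        if abs(sum(v.values()) - 1.0) > 1e-8:
            raise ValueError("family_design proportions must sum to 1")
        return v


class CompareModel(BaseModel):
    pair: tuple[str, str] = ("direct", "population")
    n_blocks: int = 100


class PipelineConfig(BaseModel):
    seed: int
    out_dir: str
    simulate: SimulateModel = Field(default_factory=SimulateModel)
    n_cohorts: int = 2
    min_cohorts_per_snp: int = 1
    compare: CompareModel = Field(default_factory=CompareModel)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _to_sim_config(model: SimulateModel, n_families: int, seed: int) -> SimulationConfig:
    strat = (
        None
        if model.strat is None
        else StratificationConfig(**model.strat.model_dump())
    )
    am = None if model.am is None else AssortativeMatingConfig(**model.am.model_dump())
    return SimulationConfig(
        n_families=n_families,
        n_snps=model.n_snps,
        maf_spec=(model.maf_low, model.maf_high),
        h2_direct=model.h2_direct,
        ige_coefficient=model.ige_coefficient,
        strat=strat,
        am=am,
        family_design=model.family_design,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Stage failures raise with the failing stage named; outputs of earlier
    stages are retained on disk.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": famgwas.__version__,
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def _stage(name):
        manifest["stages"][name] = {"status": "running"}

    def _done(name, **info):
        manifest["stages"][name] = {"status": "done", **info}

    root_rng = np.random.default_rng(config.seed)
    cohort_seeds = root_rng.integers(0, 2**31 - 1, size=config.n_cohorts)

    try:
        _stage("simulate")
        per_cohort = max(config.simulate.n_families // config.n_cohorts, 1)
        datasets = []
        for j, seed in enumerate(cohort_seeds):
            sim_cfg = _to_sim_config(config.simulate, per_cohort, int(seed))
            ds = (
                simulate_assortative_mating(sim_cfg)
                if sim_cfg.am is not None
                else simulate_random_mating(sim_cfg)
            )
            paths = fio.write_dataset(ds, out / f"cohort{j}")
            datasets.append((f"cohort{j}", ds, paths))
        _done(
            "simulate",
            files={f"{cid}_{k}": str(p) for cid, _, ps in datasets for k, p in ps.items()},
            hashes={
                f"{cid}_{k}": fio.file_sha256(p)
                for cid, _, ps in datasets
                for k, p in ps.items()
            },
        )

        _stage("qc")
        qc = {}
        for cid, ds, _ in datasets:
            rep = mendelian_consistency_report(ds)
            qc[cid] = {
                "n_violations": rep["n_violations"],
                "sib_correlation": rep["sib_correlation"],
                "flagged": rep["sib_correlation_flag"],
            }
            if rep["n_violations"] > 0:
                raise RuntimeError(f"{cid}: {rep['n_violations']} Mendelian violations")
        _done("qc", reports=qc)

        _stage("gwas")
        sumstats_paths = {}
        frames = []
        for cid, ds, _ in datasets:
            ss = run_fgwas(ds)
            p = out / f"{cid}.sumstats.tsv"
            fio.write_sumstats(ss, p)
            sumstats_paths[cid] = str(p)
            frames.append((cid, ss))
        _done(
            "gwas",
            files=sumstats_paths,
            skipped={cid: ss.attrs.get("skipped", {}) for cid, ss in frames},
        )

        _stage("meta")
        cohorts = [cohort_from_sumstats(cid, ss) for cid, ss in frames]
        meta = meta_analyze(cohorts, min_cohorts=config.min_cohorts_per_snp)
        meta_path = out / "meta.sumstats.tsv"
        meta.to_csv(meta_path, sep="\t", index=False, na_rep="NA")
        _done("meta", file=str(meta_path), n_snps=len(meta), dropped=meta.attrs["dropped"])

        _stage("compare")
        series = series_from_sumstats(
            meta, pair=config.compare.pair, n_blocks=config.compare.n_blocks
        )
        result = compare_effects(series)
        report_path = out / "compare.json"
        with open(report_path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        _done("compare", file=str(report_path), **result.to_dict())
    except Exception as exc:
        failing = next(
            (k for k, v in manifest["stages"].items() if v.get("status") == "running"),
            "unknown",
        )
        manifest["failed_stage"] = failing
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {failing!r}: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
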