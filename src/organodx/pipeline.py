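"""End-to-end orchestration: simulate -> fit -> classify -> signatures ->
connectivity -> concordance, driven by one validated JSON config.

Every stage is a pure function of its inputs, the config and the seed, so a
re-run with an identical config reproduces byte-identical outputs.  The run
directory receives per-stage CSV/JSON artifacts, a machine-readable
``summary.json`` and a log file with ISO timestamps and the resolved config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import concordance as cc
from . import connectivity as cx
from . import dose_response as dr
from . import signatures as sg
from . import synthetic as syn
from . import xenograft as xg

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineError"]

logger = logging.getLogger("organodx")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""


class ScreenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pdos: int = 42
    dose_grid: tuple[float, ...] = syn.PAPER_DOSE_GRID
    n_replicates: int = 4
    noise_sd: float = 5.0
    log10_ic50_range: tuple[float, float] = (0.14, 2.0)


class CountConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_group_a: int = 8
    n_group_b: int = 8
    n_features: int = 2000
    n_planted: int = 20
    planted_log2fc: float = 3.0
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.7, 1.4)


class XenoConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_arm: int = 5
    v0_range: tuple[float, float] = (80.0, 100.0)
    growth_rate_control: float = 0.12
    growth_rate_treated: float = 0.04
    measurement_days: tuple[float, ...] = tuple(range(0, 28, 3))
    noise_cv: float = 0.1


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = 17
    p_class_sensitive: float = 9 / 17
    p_respond_given_sensitive: float = 0.78
    p_respond_given_resistant: float = 0.37


class ConnectivityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_random_perturbagens: int = 20
    n_reversers: int = 3
    query_top_n: int = 150
    threshold: float = -95.0


class RunConfig(BaseModel):
    """Full pipeline configuration with the study constants as defaults."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "organodx_run"
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate",
        "dose_response",
        "tgi",
        "signatures",
        "connectivity",
        "concordance",
    )
    screen: ScreenConfig = Field(default_factory=ScreenConfig)
    counts: CountConfig = Field(default_factory=CountConfig)
    xeno: XenoConfig = Field(default_factory=XenoConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    connectivity: ConnectivityConfig = Field(default_factory=ConnectivityConfig)
    boundaries: tuple[float, float, float, float, float] = dr.DEFAULT_BOUNDARIES
    top_k: int = 100
    tgi_cutoff: float = 50.0

    @field_validator("boundaries")
    @classmethod
    def _boundaries_increasing(cls, v):
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("boundaries must be strictly increasing")
        return v


def validate_config(path) -> RunConfig:
    """Load and schema-check a JSON config, filling defaults.

    An empty JSON object yields the fully defaulted configuration; schema
    violations raise with the offending key in the message.
    """
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig.model_validate(data)


def _draw_truths(cfg: ScreenConfig, seed: int) -> tuple:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    lo, hi = cfg.log10_ic50_range
    truths = []
    for _ in range(cfg.n_pdos):
        top = rng.uniform(95.0, 105.0)
        bottom = rng.uniform(0.0, 30.0)
        hill = rng.uniform(0.8, 3.0)
        ic50 = 10.0 ** rng.uniform(lo, hi)
        truths.append((top, bottom, hill, ic50))
    return tuple(truths)


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    seed = config.seed
    truths = _draw_truths(config.screen, seed)
    scen = syn.ScreenScenario(
        fourpl_truth=truths,
        dose_grid=config.screen.dose_grid,
        n_replicates=config.screen.n_replicates,
        noise_sd=config.screen.noise_sd,
        seed=seed,
    )
    plates = [syn.gen_dose_plate(scen, i) for i in range(config.screen.n_pdos)]
    dr.write_plates(plates, out / "plates.csv")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    planted = tuple(
        sorted(rng.choice(config.counts.n_features, size=config.counts.n_planted, replace=False))
    )
    # plant both directions so the derived signature has up and down arms
    signs = np.where(np.arange(len(planted)) % 2 == 0, 1.0, -1.0)
    counts = syn.gen_counts(
        syn.CountScenario(
            n_group_a=config.counts.n_group_a,
            n_group_b=config.counts.n_group_b,
            n_features=config.counts.n_features,
            planted_idx=planted,
            planted_log2fc=tuple(signs * config.counts.planted_log2fc),
            baseline_mean=config.counts.baseline_mean,
            dispersion=config.counts.dispersion,
            size_factor_range=config.counts.size_factor_range,
            seed=seed,
        )
    )
    counts.write(out / "counts.tsv", out / "labels.csv")

    course = syn.gen_xeno_course(
        syn.XenoScenario(seed=seed, **config.xeno.model_dump())
    )
    course.write_csv(out / "xeno.csv")

    patients = syn.gen_cohort(syn.CohortScenario(seed=seed, **config.cohort.model_dump()))
    patients.to_csv(out / "cohort.csv", index=False)

    state.update(plates=plates, counts=counts, course=course, patients=patients,
                 planted=[counts.feature_ids[i] for i in planted])
    return {
        "n_plates": len(plates),
        "n_samples": len(counts.sample_ids),
        "n_features": len(counts.feature_ids),
        "planted_features": state["planted"],
        "n_mice": int(course.data["mouse_id"].nunique()),
        "n_patients": len(patients),
    }


def _stage_dose_response(config: RunConfig, out: Path, state: dict) -> dict:
    if "plates" not in state:
        state["plates"] = dr.read_plates(out / "plates.csv")
    table = dr.fit_plate_table(state["plates"], config.boundaries)
    table.to_csv(out / "fits.csv", index=False)
    state["fit_table"] = table
    return {
        "n_fit": len(table),
        "category_counts": table["category"].value_counts().to_dict(),
        "group_counts": table["group"].value_counts().to_dict(),
        "median_ic50_uM": float(table["ic50_uM"].median()),
    }


def _stage_tgi(config: RunConfig, out: Path, state: dict) -> dict:
    if "course" not in state:
        state["course"] = xg.TumorCourse.read_csv(out / "xeno.csv")
    course = state["course"]
    result = xg.compute_tgi(course, cutoff=config.tgi_cutoff)
    xg.summarize_arms(course).to_csv(out / "xeno_medians.csv", index=False)
    payload = {
        "tgi_pct": result.tgi_pct,
        "responder": result.responder,
        "endpoint_day": result.endpoint_day,
    }
    (out / "tgi.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


def _stage_signatures(config: RunConfig, out: Path, state: dict) -> dict:
    if "counts" not in state:
        state["counts"] = sg.CountMatrix.read(out / "counts.tsv", out / "labels.csv")
    counts = state["counts"]
    de_table = sg.de_rank(counts)
    de_table.to_csv(out / "de_table.csv", index=False)
    consensus = sg.loocv_consensus(counts, k=config.top_k)
    (out / "consensus.json").write_text(
        json.dumps(
            {"fold_tops": consensus.fold_tops, "consensus": consensus.consensus,
             "k": consensus.k, "n_folds": consensus.n_folds},
            indent=2, sort_keys=True,
        )
    )
    models = sg.single_feature_lr_search(counts, consensus.consensus)
    import pandas as pd

    pd.DataFrame([m.__dict__ for m in models]).to_csv(out / "predictors.csv", index=False)
    sg.export_signature(de_table, consensus, out)
    state.update(de_table=de_table, consensus=consensus, models=models)
    return {
        "consensus_size": len(consensus.consensus),
        "n_folds": consensus.n_folds,
        "n_models_score_1": sum(1 for m in models if m.loocv_score == 1.0),
        "consensus": consensus.consensus,
    }


def _synthetic_reference_profiles(
    signed_order: list[str], cfg: ConnectivityConfig, seed: int
) -> list[cx.ReferenceProfile]:
    """A stand-in reference collection: random perturbagens plus planted
    signature reversers.

    ``signed_order`` ranks features most-up-regulated-in-OR first; a reverser
    instance is that ranking reversed with mild rank jitter, i.e. a
    perturbagen whose expression response opposes the resistance phenotype.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    n = len(signed_order)
    profiles = []
    for i in range(cfg.n_random_perturbagens):
        order = list(signed_order)
        rng.shuffle(order)
        profiles.append(cx.ReferenceProfile(f"random{i + 1:02d}", tuple(order)))
    reversed_order = np.array(signed_order[::-1])
    for i in range(cfg.n_reversers):
        jitter = np.arange(n) + rng.normal(0.0, 0.02 * n, size=n)
        profiles.append(
            cx.ReferenceProfile(f"reverser{i + 1:02d}", tuple(reversed_order[np.argsort(jitter)]))
        )
    return profiles


def _stage_connectivity(config: RunConfig, out: Path, state: dict) -> dict:
    needed = out / "signature_up.txt"
    if "de_table" not in state:
        if not needed.exists():
            raise PipelineError(
                "connectivity requires the signatures stage (missing signature_up.txt / "
                "signature_down.txt query files)"
            )
        query_a = cx.QuerySignature.read(out / "signature_up.txt", out / "signature_down.txt")
        de_table = None
        signed_order = sorted(query_a.up_set) + sorted(query_a.down_set)
    else:
        de_table = state["de_table"]
        consensus = state["consensus"]
        annotated = consensus.consensus_with_direction(de_table)
        up = frozenset(annotated.loc[annotated["direction"] == "up", "feature_id"])
        down = frozenset(annotated.loc[annotated["direction"] == "down", "feature_id"])
        query_a = cx.QuerySignature(up, down)
        n = config.connectivity.query_top_n
        by_t = de_table.sort_values(by=["t_stat", "feature_id"], ascending=[False, True])
        query_b = cx.QuerySignature(
            frozenset(by_t["feature_id"].head(n)), frozenset(by_t["feature_id"].tail(n))
        )
        signed_order = by_t["feature_id"].tolist()
    profiles = _synthetic_reference_profiles(signed_order, config.connectivity, config.seed)
    cx.write_profiles(profiles, out / "reference_profiles.tsv")
    hits_a = cx.score_profiles(query_a, profiles)
    hits_b = cx.score_profiles(query_b if de_table is not None else query_a, profiles)
    candidates = cx.select_candidates(hits_a, hits_b, config.connectivity.threshold)
    candidates.to_csv(out / "candidates.csv", index=False)
    state["candidates"] = candidates
    return {
        "n_profiles": len(profiles),
        "n_passing_a": sum(1 for h in hits_a if h.score <= config.connectivity.threshold),
        "n_passing_b": sum(1 for h in hits_b if h.score <= config.connectivity.threshold),
        "candidates": candidates["perturbagen_id"].tolist(),
    }


def _stage_concordance(config: RunConfig, out: Path, state: dict) -> dict:
    import pandas as pd

    if "patients" not in state:
        state["patients"] = pd.read_csv(out / "cohort.csv")
    table = cc.Cohort2x2.from_patients(state["patients"])
    metrics = cc.confusion_metrics(table)
    payload = {
        "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "metrics": metrics,
        "fisher_p": cc.fisher_exact(table),
    }
    (out / "concordance.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


_STAGES = {
    "simulate": _stage_simulate,
    "dose_response": _stage_dose_response,
    "tgi": _stage_tgi,
    "signatures": _stage_signatures,
    "connectivity": _stage_connectivity,
    "concordance": _stage_concordance,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write summary.json.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are retained alongside a ``FAILED`` marker file.
    """
    unknown = set(config.stages) - set(_STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("resolved config: %s", config.model_dump_json())

    summary: dict = {"config": config.model_dump(), "stages": {}}
    state: dict = {}
    try:
        for name in (s for s in _STAGES if s in config.stages):
            logger.info("stage %s: start", name)
            try:
                summary["stages"][name] = _STAGES[name](config, out, state)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
            logger.info("stage %s: done", name)
    except PipelineError as err:
        (out / "FAILED").write_text(str(err) + "\n")
        logger.error("%s", err)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary
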