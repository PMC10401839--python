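"""End-to-end per-sex analysis pipeline.

One call runs: roster acquisition (CSV or synthetic preset) -> sex
stratification -> one-hot encoding -> K sweep with restarts -> model-number
selection -> affiliation -> cluster profiles at tau -> descriptive table,
and writes every stage artifact plus a run manifest into an output
directory.  All randomness derives from one root seed, so two runs with
the same configuration produce byte-identical model JSONs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .characterize import DEFAULT_TAU, affiliation, characterize, profiles_to_json
from .codebook import SEXES, default_codebook
from .descriptives import descriptive_table
from .encoding import encode, stratify_by_sex
from .integrate import joint_display, read_responses
from .plsa import FitConfig
from .selection import SelectionPolicy, select_k, sweep_k
from .synthetic import generate_roster, spec_from_json, table1_preset

logger = logging.getLogger("segmint")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and stratum."""


@dataclass
class PipelineConfig:
    """Validated run configuration (see :func:`load_config` for the YAML form)."""

    output_dir: str
    seed: int = 0
    roster_path: str | None = None
    preset: str | None = None  # "table1"
    spec_path: str | None = None
    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-8
    criterion: str = "bic"
    scope: str = "class"
    min_cluster_n_floor: int = 10
    tie_tolerance: float = 0.0
    tau: float = DEFAULT_TAU
    responses: dict[str, str] = field(default_factory=dict)  # sex -> CSV path

    def validate(self) -> None:
        sources = [s for s in (self.roster_path, self.preset, self.spec_path) if s]
        if len(sources) != 1:
            raise PipelineError(
                "exactly one input source required: roster, preset, or spec"
            )
        if self.preset is not None and self.preset != "table1":
            raise PipelineError(f"unknown preset {self.preset!r}; available: table1")
        if not 0 < self.tau <= 1:
            raise PipelineError(f"tau must be in (0, 1], got {self.tau}")
        FitConfig(
            max_iter=self.max_iter, tol=self.tol, n_restarts=self.n_restarts, seed=self.seed
        ).validate()
        SelectionPolicy(
            criterion=self.criterion,
            scope=self.scope,
            min_cluster_n_floor=self.min_cluster_n_floor,
            tie_tolerance=self.tie_tolerance,
        ).validate()
        for sex in self.responses:
            if sex not in SEXES:
                raise PipelineError(f"responses key {sex!r} is not a sex")


_YAML_KEYS = {
    "output_dir": str,
    "seed": int,
    "roster": str,
    "preset": str,
    "spec": str,
    "sweep": dict,
    "selection": dict,
    "tau": (int, float),
    "responses": dict,
}
_SWEEP_KEYS = {"k_min": int, "k_max": int, "restarts": int, "max_iter": int, "tol": float}
_SELECTION_KEYS = {
    "criterion": str,
    "scope": str,
    "min_cluster_n_floor": int,
    "tie_tolerance": (int, float),
}


def load_config(path) -> PipelineConfig:
    """Parse and validate a pipeline YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineError("config YAML must be a mapping")
    for key, val in raw.items():
        if key not in _YAML_KEYS:
            raise PipelineError(f"unknown config key {key!r}")
        if val is not None and not isinstance(val, _YAML_KEYS[key]):
            raise PipelineError(f"config key {key!r} has wrong type")
    for sub, allowed in (("sweep", _SWEEP_KEYS), ("selection", _SELECTION_KEYS)):
        for key, val in (raw.get(sub) or {}).items():
            if key not in allowed:
                raise PipelineError(f"unknown config key {sub}.{key!r}")
            if not isinstance(val, allowed[key]) or isinstance(val, bool):
                raise PipelineError(f"config key {sub}.{key!r} has wrong type")
    if "output_dir" not in raw:
        raise PipelineError("config must set output_dir")
    sweep = raw.get("sweep") or {}
    sel = raw.get("selection") or {}
    cfg = PipelineConfig(
        output_dir=raw["output_dir"],
        seed=raw.get("seed", 0),
        roster_path=raw.get("roster"),
        preset=raw.get("preset"),
        spec_path=raw.get("spec"),
        k_min=sweep.get("k_min", 2),
        k_max=sweep.get("k_max", 10),
        n_restarts=sweep.get("restarts", 5),
        max_iter=sweep.get("max_iter", 500),
        tol=sweep.get("tol", 1e-8),
        criterion=sel.get("criterion", "bic"),
        scope=sel.get("scope", "class"),
        min_cluster_n_floor=sel.get("min_cluster_n_floor", 10),
        tie_tolerance=sel.get("tie_tolerance", 0.0),
        tau=raw.get("tau", DEFAULT_TAU),
        responses=raw.get("responses") or {},
    )
    cfg.validate()
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: v for k, v in vars(config).items()}, sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full per-sex pipeline; return the artifact bundle.

    The bundle maps each processed sex to its sweep table, selected K,
    fitted model, profiles and descriptive table, and records output file
    paths.  Stage failures abort with the stage and stratum in the error;
    artifacts written before the failure are kept alongside a FAILED
    marker file.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    stage = "input"
    stratum = "-"
    try:
        t0 = time.time()
        if config.preset == "table1":
            spec = table1_preset(seed=config.seed)
            roster, truth = generate_roster(spec)
            truth.assignments.to_csv(out / "ground_truth.csv", index=False)
        elif config.spec_path:
            spec = spec_from_json(config.spec_path)
            spec.seed = config.seed
            roster, truth = generate_roster(spec)
            truth.assignments.to_csv(out / "ground_truth.csv", index=False)
        else:
            roster = pd.read_csv(config.roster_path, dtype=str)
        codebook = default_codebook()
        roster.to_csv(out / "roster.csv", index=False)
        codebook.to_json(out / "codebook.json")
        timings["input"] = time.time() - t0

        stage = "descriptives"
        t0 = time.time()
        desc = descriptive_table(roster, codebook)
        desc.to_csv(out / "descriptives.csv")
        timings["descriptives"] = time.time() - t0

        stage = "stratify"
        male, female = stratify_by_sex(roster)
        strata = {"male": male, "female": female}

        bundle: dict = {"roster": roster, "descriptives": desc, "paths": {}, "strata": {}}
        policy = SelectionPolicy(
            criterion=config.criterion,
            scope=config.scope,
            min_cluster_n_floor=config.min_cluster_n_floor,
            tie_tolerance=config.tie_tolerance,
        )
        joint_rows = []
        for sex, sub in strata.items():
            stratum = sex
            if len(sub) == 0:
                logger.info("[%s] empty stratum; skipped", sex)
                continue
            stage = "encode"
            t0 = time.time()
            matrix = encode(sub, codebook)
            timings[f"{sex}.encode"] = time.time() - t0

            stage = "sweep"
            t0 = time.time()
            fit_cfg = FitConfig(
                max_iter=config.max_iter,
                tol=config.tol,
                n_restarts=config.n_restarts,
                seed=config.seed,
            )
            k_max = min(config.k_max, min(matrix.shape))
            sweep = sweep_k(matrix, config.k_min, k_max, fit_cfg)
            sweep.to_csv(out / f"sweep_{sex}.csv")
            timings[f"{sex}.sweep"] = time.time() - t0
            logger.info("[%s] sweep K=%d..%d done", sex, config.k_min, k_max)

            stage = "select"
            k_sel = select_k(sweep, policy)
            model = sweep.models[k_sel]
            model.to_json(out / f"model_{sex}.json")
            logger.info("[%s] selected K=%d (criterion %s)", sex, k_sel, policy.column)

            stage = "characterize"
            t0 = time.time()
            affil = affiliation(model)
            profiles = characterize(affil, tau=config.tau)
            profiles_to_json(profiles, out / f"profiles_{sex}.json")
            affil.to_long_frame().to_csv(out / f"affiliation_{sex}.csv", index=False)
            timings[f"{sex}.characterize"] = time.time() - t0

            if sex in config.responses:
                stage = "integrate"
                responses = read_responses(config.responses[sex])
                joint_rows.append(joint_display(profiles, responses, sex))

            bundle["strata"][sex] = {
                "matrix": matrix,
                "sweep": sweep,
                "selected_k": k_sel,
                "model": model,
                "affiliation": affil,
                "profiles": profiles,
            }
        stratum = "-"
        if joint_rows:
            stage = "integrate"
            jd = pd.concat(joint_rows, ignore_index=True)
            jd.to_csv(out / "joint_display.csv", index=False)
            bundle["joint_display"] = jd

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": {k: v for k, v in vars(config).items()},
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "selected_k": {
                sex: bundle["strata"][sex]["selected_k"] for sex in bundle["strata"]
            },
            "winning_restart_seeds": {
                sex: bundle["strata"][sex]["model"].seed for sex in bundle["strata"]
            },
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "elapsed_s": round(time.time() - t_start, 3),
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        with open(out / "timings.json", "w", encoding="utf-8") as fh:
            json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=2)
        bundle["manifest"] = manifest
        bundle["paths"] = {p.name: str(p) for p in out.iterdir() if p.is_file()}
        return bundle
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage} stratum={stratum}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed for stratum {stratum!r}: {exc}") from exc
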