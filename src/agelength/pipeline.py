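"""End-to-end pipeline: error summary -> model fit -> simulation -> classification.

Driven by a single YAML/dict configuration; one root seed spawns
deterministic per-stage substreams so any stage can be rerun in isolation
without disturbing the others' draws.  Every run writes a manifest
(config hash + seed + artifact list) sufficient to reproduce all numeric
outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import age_structure, io, length_models, photogrammetry, uas_simulator

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline", "load_config"]

#: Per-stage SeedSequence spawn keys (stable across runs and stage subsets).
_STAGE_KEY = {"simulate": 0, "classify": 1, "synth": 2}

_FITTERS = {
    "ratio": length_models.fit_ratio_model,
    "linear": length_models.fit_linear_model,
    "loglinear": length_models.fit_loglinear_model,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} did not parse to a mapping")
    return cfg


def stage_seed(root_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage substream of the root seed."""
    return np.random.SeedSequence(root_seed, spawn_key=(_STAGE_KEY[stage],))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _noise_specs(cfg: dict) -> tuple[uas_simulator.NoiseSpec, uas_simulator.NoiseSpec]:
    noise = cfg.get("noise", {})
    b = noise.get("bhdf", {})
    t = noise.get("tl", {})
    return (
        uas_simulator.NoiseSpec(b.get("mean", 0.0), b.get("sd", 0.031), "BHDF"),
        uas_simulator.NoiseSpec(t.get("mean", 0.0), t.get("sd", 0.031), "TL"),
    )


@dataclass
class Manifest:
    config_hash: str
    seed: int
    artifacts: list[str]

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {"config_hash": self.config_hash, "seed": self.seed, "artifacts": self.artifacts},
                indent=2,
                sort_keys=True,
            )
        )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the manifest as a dict.

    Stages (each optional except model fitting + classification):
      1. photogrammetry error summary, if ``measurements`` is configured;
      2. TL~BHDF model fit on ``morphometrics``;
      3. optional full simulated dataset dump (``write_simulated``);
      4. classification for every requested scenario and measure.

    Any failure raises :class:`PipelineError` naming the stage; artifacts
    written before the failure are retained next to a ``.partial`` marker.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir or cfg.get("output_dir", "agelength_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    if seed is None:
        raise PipelineError("config", "a seed is required whenever stochastic stages run")
    artifacts: list[str] = []
    partial_marker = out / ".partial"
    partial_marker.write_text("pipeline in progress\n")

    try:
        # -- stage: photogrammetry error summary -------------------------
        if cfg.get("measurements"):
            try:
                meas = io.load_measurements(cfg["measurements"])
                groups = photogrammetry.summarize_measurement_error(
                    meas,
                    group_keys=cfg.get("error_group_keys", ["measure_kind", "behavior"]),
                )
                report = photogrammetry.error_report(
                    groups, cfg.get("error_group_keys", ["measure_kind", "behavior"])
                )
                path = out / "error_report.csv"
                report.to_csv(path, index=False)
                artifacts.append(path.name)
            except (ValueError, KeyError, OSError) as e:
                raise PipelineError("error_summary", str(e)) from e

        # -- stage: model fit ---------------------------------------------
        try:
            morph_path = cfg.get("morphometrics")
            if not morph_path:
                raise ValueError("config key 'morphometrics' (input CSV) is required")
            records = io.load_morphometrics(morph_path)
            kind = cfg.get("model", "loglinear")
            if kind not in _FITTERS:
                raise ValueError(f"unknown model kind {kind!r}")
            model = _FITTERS[kind](records, per_animal=cfg.get("fit_per_animal", False))
            path = out / "model_card.json"
            path.write_text(json.dumps(model.to_card(), indent=2, sort_keys=True))
            artifacts.append(path.name)
        except (ValueError, OSError) as e:
            raise PipelineError("fit", str(e)) from e

        bhdf_noise, tl_noise = _noise_specs(cfg)
        n_replicates = int(cfg.get("n_replicates", 1000))

        # -- stage: optional simulated-dataset dump -----------------------
        if cfg.get("write_simulated"):
            try:
                sim = uas_simulator.simulate_dataset_frame(
                    records, model, bhdf_noise, tl_noise,
                    min(n_replicates, int(cfg.get("simulated_replicates", 10))),
                    stage_seed(seed, "simulate"),
                )
                path = out / "simulated.csv"
                sim.to_csv(path, index=False)
                artifacts.append(path.name)
            except ValueError as e:
                raise PipelineError("simulate", str(e)) from e

        # -- stage: classification ---------------------------------------
        scenarios = age_structure.builtin_scenarios()
        requested = cfg.get("scenarios", list(scenarios))
        measures = cfg.get("measures", ["TL", "BHDF"])
        performance = {}
        try:
            classify_ss = stage_seed(seed, "classify")
            children = classify_ss.spawn(len(requested) * len(measures))
            i = 0
            for name in requested:
                if name not in scenarios:
                    raise ValueError(f"unknown scenario {name!r}")
                for measure in measures:
                    perf = age_structure.run_classifier_experiment(
                        records,
                        scenarios[name],
                        model,
                        bhdf_noise,
                        tl_noise,
                        n_replicates=n_replicates,
                        measure=measure,
                        mode=cfg.get("mode", "probabilistic"),
                        seed=children[i],
                        truncate=cfg.get("truncate", False),
                    )
                    i += 1
                    cpath = out / f"confusion_{name}_{measure}.csv"
                    perf.confusion_frame().to_csv(cpath)
                    artifacts.append(cpath.name)
                    performance[f"{name}/{measure}"] = perf.to_dict()
            ppath = out / "performance.json"
            ppath.write_text(json.dumps(performance, indent=2, sort_keys=True))
            artifacts.append(ppath.name)
        except ValueError as e:
            raise PipelineError("classify", str(e)) from e

        manifest = Manifest(_config_hash(cfg), int(seed), sorted(artifacts))
        manifest.write(out / "manifest.json")
        partial_marker.unlink(missing_ok=True)
        return {"config_hash": manifest.config_hash, "seed": manifest.seed, "artifacts": manifest.artifacts}
    except PipelineError:
        logger.error("pipeline failed; partial outputs retained in %s", out)
        raise
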