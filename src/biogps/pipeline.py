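"""Declarative pipeline runner binding the stages together.

A pipeline config (YAML/dict) names an output directory, a seed and the
stages to run in dependency order: ``simulate -> admix -> curate -> predict
-> accuracy``. Each stage block holds that stage's parameters; unknown top
level or stage keys are rejected, and referenced input files are checked
before any stage runs. Every artifact gets a JSON metadata sidecar.

Example::

    seed: 1
    out_dir: out/
    stages:
      simulate: {n_populations: 12, n_per_population: 8, n_loci: 500}
      admix: {}          # uses the simulated genotypes + true frequencies
      predict: {M: 10}
      accuracy: {thresholds_km: [250, 500]}
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np

from .admixture import SupervisedAdmixture
from .curation import CurationConfig, curate_panel
from .errors import ConfigurationError
from .gps import GeographicPositioning, SiteRegionOracle, assignment_accuracy
from . import io as bio
from .world import WorldConfig, make_world

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

_TOP_KEYS = {"seed", "out_dir", "stages", "verbosity"}
_STAGES = ("simulate", "admix", "curate", "predict", "accuracy")
_STAGE_KEYS = {
    "simulate": {f.name for f in dataclasses.fields(WorldConfig)},
    "admix": {"genotypes", "frequencies", "tol", "max_iter", "out"},
    "curate": {
        "panel",
        "accept_ratio",
        "ratio_mode",
        "retain_km",
        "target_accuracy",
        "max_rounds",
        "n_neighbors",
        "out",
        "report",
    },
    "predict": {"panel", "q_matrix", "M", "weight_power", "out"},
    "accuracy": {"predictions", "truth", "thresholds_km", "out"},
}


def _validate(config: Mapping, base: Path) -> dict:
    cfg = dict(config)
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    stages = cfg.get("stages")
    if not isinstance(stages, Mapping) or not stages:
        raise ConfigurationError("stages: at least one stage block required")
    for name, block in stages.items():
        if name not in _STAGES:
            raise ConfigurationError(f"stages: unknown stage {name!r}")
        block = block or {}
        bad = set(block) - _STAGE_KEYS[name]
        if bad:
            raise ConfigurationError(f"stages.{name}: unknown keys {sorted(bad)}")
        for key in ("genotypes", "frequencies", "panel", "q_matrix", "predictions", "truth"):
            val = block.get(key)
            if val is not None and not (base / val).exists():
                raise ConfigurationError(f"stages.{name}.{key}: file not found: {val}")
    return cfg


def run_pipeline(config: Mapping, base_dir=".") -> dict[str, dict]:
    """Validate and execute a pipeline config; returns per-stage artifact maps."""
    base = Path(base_dir)
    cfg = _validate(config, base)
    seed = int(cfg.get("seed", 0))
    out_dir = base / cfg.get("out_dir", "biogps_out")
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: Mapping = cfg["stages"]
    artifacts: dict[str, dict] = {}
    world = None

    if "simulate" in stages:
        block = dict(stages["simulate"] or {})
        block.setdefault("seed", seed)
        wc = WorldConfig(**block)
        world = make_world(wc)
        paths = bio.write_world(world, out_dir)
        artifacts["simulate"] = {k: str(v) for k, v in paths.items()}
        logger.info("simulate: wrote %d artifacts to %s", len(paths), out_dir)

    def _resolve(block, key, default_artifact):
        if block.get(key):
            return base / block[key]
        sim = artifacts.get("simulate", {})
        if default_artifact in sim:
            return Path(sim[default_artifact])
        raise ConfigurationError(f"{key}: not given and no simulated artifact available")

    if "admix" in stages:
        block = dict(stages["admix"] or {})
        ids, G = bio.read_genotypes(_resolve(block, "genotypes", "genotypes"))
        labels, F = bio.read_frequencies(_resolve(block, "frequencies", "frequencies"))
        est = SupervisedAdmixture(
            tol=float(block.get("tol", 1e-7)), max_iter=int(block.get("max_iter", 2000))
        ).fit(F, component_labels=labels)
        Q = est.transform(G)
        out = out_dir / block.get("out", "Q_estimated.txt")
        bio.write_q_matrix(Q, out)
        bio.write_sidecar(out, {"seed": seed, "stage": "admix", "tol": est.tol})
        artifacts["admix"] = {"q_matrix": str(out)}
        logger.info("admix: estimated %d individuals", Q.shape[0])

    def _panel_oracle(panel):
        return SiteRegionOracle({p.name: [p.location] for p in panel})

    if "curate" in stages:
        block = dict(stages["curate"] or {})
        panel = bio.read_panel(_resolve(block, "panel", "panel"))
        cc = CurationConfig(
            **{
                k: block[k]
                for k in ("accept_ratio", "ratio_mode", "retain_km", "target_accuracy", "max_rounds", "n_neighbors")
                if k in block
            }
        )
        curated, report = curate_panel(panel, cc, oracle=_panel_oracle(panel), seed=seed)
        out = out_dir / block.get("out", "curated_panel.csv")
        bio.write_panel(curated, out)
        rpt = out_dir / block.get("report", "curation_report.json")
        rpt.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        bio.write_sidecar(out, {"seed": seed, "stage": "curate"})
        artifacts["curate"] = {"panel": str(out), "report": str(rpt)}

    if "predict" in stages:
        block = dict(stages["predict"] or {})
        panel = bio.read_panel(_resolve(block, "panel", "panel"))
        qpath = (
            base / block["q_matrix"]
            if block.get("q_matrix")
            else Path(artifacts.get("admix", artifacts.get("simulate", {})).get("q_matrix"))
        )
        Q = bio.read_q_matrix(qpath)
        engine = GeographicPositioning(
            n_neighbors=int(block.get("M", 10)), weight_power=float(block.get("weight_power", 4.0))
        ).fit_panel(panel)
        ids = world.individual_ids if world is not None else [f"ind{i}" for i in range(Q.shape[0])]
        results = engine.predict_result(Q, ids=ids)
        out = out_dir / block.get("out", "predictions.csv")
        bio.write_predictions(results, out)
        bio.write_sidecar(out, {"seed": seed, "stage": "predict", "M": engine.n_neighbors})
        artifacts["predict"] = {"predictions": str(out)}

    if "accuracy" in stages:
        block = dict(stages["accuracy"] or {})
        pred_path = (
            base / block["predictions"]
            if block.get("predictions")
            else Path(artifacts["predict"]["predictions"])
        )
        import pandas as pd

        pred = pd.read_csv(pred_path, dtype={"id": str})
        truth = bio.read_truth(_resolve(block, "truth", "truth"))
        if "region" not in truth.columns:
            raise ConfigurationError("accuracy: truth file must carry a region column")
        sites: dict[str, list] = {}
        for _id, row in truth.iterrows():
            sites.setdefault(str(row["region"]), []).append((row["lat"], row["lon"]))
        oracle = SiteRegionOracle(sites)
        from .gps import PredictionResult

        results = [
            PredictionResult(str(r.id), (r.lat, r.lon), [], getattr(r, "best_population", ""))
            for r in pred.itertuples()
        ]
        acc = assignment_accuracy(
            results,
            {str(i): str(r) for i, r in truth["region"].items()},
            oracle,
            [float(t) for t in block.get("thresholds_km", (250, 500))],
        )
        out = out_dir / block.get("out", "accuracy.json")
        out.write_text(json.dumps({str(k): v for k, v in acc.items()}, indent=2) + "\n")
        artifacts["accuracy"] = {"accuracy": str(out), **{str(k): v for k, v in acc.items()}}

    return artifacts
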