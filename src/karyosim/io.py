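"""Configuration files, output export and the run manifest.

Configuration is one YAML mapping with all reference-experiment defaults
pre-filled, so a minimal file (or bare CLI flags) runs the standard setup.
Exports are plain CSV/JSON whose schemas round-trip exactly through pandas.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .dynamics import RateParams, SimulationConfig, Trajectory
from .exceptions import ConfigurationError
from .experiments import CohortSpec, CohortSummary, compare_cohorts
from .karyotype import GeneDistribution
from .therapy import TherapyPlan

__all__ = [
    "RunManifest",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "dump_config",
    "export_trajectory",
    "export_cohort",
    "export_comparison",
]

_CONFIG_KEYS = {
    "distribution", "chromosomes", "scenario", "alpha", "delta", "mu",
    "dose_response", "missegregation_sampling", "crowding_division_scale",
    "initial_population", "capacity", "detection_threshold", "max_population",
    "max_steps", "surgery_keep_head", "surgery_removal", "chemo_rounds",
    "seed", "replicates", "record_composition", "schema_version",
}


@dataclass(frozen=True)
class RunManifest:
    """Inventory of one export: config hash, seeds, files, provenance."""

    config_hash: str
    seeds: list[int]
    files: list[str]
    created: str
    version: str = __version__

    def to_dict(self) -> dict:
        return asdict(self)


def _distribution(raw: dict) -> GeneDistribution:
    if "chromosomes" in raw and raw["chromosomes"] is not None:
        contents = [tuple(int(x) for x in row) for row in raw["chromosomes"]]
        return GeneDistribution.custom(contents, name=str(raw.get("distribution", "custom")))
    return GeneDistribution.from_name(str(raw.get("distribution", "A")))


def config_from_dict(raw: dict) -> Union[SimulationConfig, CohortSpec]:
    """Validate a raw mapping into a config, filling reference defaults.

    Returns a :class:`CohortSpec` when ``replicates`` is given (and > 1),
    otherwise a single-run :class:`SimulationConfig`.  Unknown keys are
    configuration errors so typos fail loudly.
    """
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    try:
        dist = _distribution(raw)
        rates = RateParams(
            alpha=float(raw.get("alpha", 0.045)),
            delta=float(raw.get("delta", 0.045)),
            mu=float(raw.get("mu", 0.02)),
            dose_response=str(raw.get("dose_response", "linear")),
            missegregation_sampling=str(raw.get("missegregation_sampling", "copy")),
            crowding_division_scale=float(raw.get("crowding_division_scale", 1.0)),
        )
        scenario = str(raw.get("scenario", "none"))
        detection = int(raw.get("detection_threshold", 1000))
        therapy: Optional[TherapyPlan] = None
        if scenario != "none":
            therapy = TherapyPlan(
                scenario=scenario,
                detection_threshold=detection,
                surgery_keep_head=int(raw.get("surgery_keep_head", 100)),
                surgery_removal=int(raw.get("surgery_removal", detection - int(raw.get("surgery_keep_head", 100)))),
                chemo_rounds=int(raw.get("chemo_rounds", 9)),
            )
        config = SimulationConfig(
            distribution=dist,
            rates=rates,
            initial_population=int(raw.get("initial_population", 100)),
            capacity=int(raw.get("capacity", 200)),
            detection_threshold=detection,
            max_population=int(raw.get("max_population", 7000)),
            max_steps=int(raw.get("max_steps", 300)),
            therapy=therapy,
            seed=int(raw.get("seed", 0)),
            record_composition=bool(raw.get("record_composition", True)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(str(exc)) from exc
    replicates = int(raw.get("replicates", 1))
    if "replicates" in raw:
        return CohortSpec(base_config=config, n_replicates=replicates)
    return config


def config_to_dict(config: Union[SimulationConfig, CohortSpec]) -> dict:
    """Serialise a config back to the flat mapping accepted by the loader."""
    replicates = None
    if isinstance(config, CohortSpec):
        replicates = config.n_replicates
        config = config.base_config
    dist = config.distribution
    raw: dict[str, Any] = {
        "schema_version": 1,
        "distribution": dist.name,
        "alpha": config.rates.alpha,
        "delta": config.rates.delta,
        "mu": config.rates.mu,
        "dose_response": config.rates.dose_response,
        "missegregation_sampling": config.rates.missegregation_sampling,
        "crowding_division_scale": config.rates.crowding_division_scale,
        "initial_population": config.initial_population,
        "capacity": config.capacity,
        "detection_threshold": config.detection_threshold,
        "max_population": config.max_population,
        "max_steps": config.max_steps,
        "seed": config.seed,
        "record_composition": config.record_composition,
        "scenario": config.therapy.scenario if config.therapy else "none",
    }
    if dist.name not in ("A", "B", "C", "unlinked"):
        raw["chromosomes"] = [list(t.content) for t in dist.chromosome_types]
    if config.therapy is not None:
        raw["surgery_keep_head"] = config.therapy.surgery_keep_head
        raw["surgery_removal"] = config.therapy.surgery_removal
        raw["chemo_rounds"] = config.therapy.chemo_rounds
    if replicates is not None:
        raw["replicates"] = replicates
    return raw


def load_config(path: Union[str, Path]) -> Union[SimulationConfig, CohortSpec]:
    """Load and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def dump_config(config: Union[SimulationConfig, CohortSpec], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: Union[SimulationConfig, CohortSpec]) -> str:
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _events_dict(traj: Trajectory) -> dict:
    return {
        "detection_step": traj.detection_step,
        "intervention_step": traj.intervention_step,
        "chemo_steps": list(traj.chemo_steps),
        "relapse_step": traj.relapse_step,
        "termination_reason": traj.termination_reason,
        "cells_at_detection": traj.cells_at_detection,
        "cells_post_surgery": traj.cells_post_surgery,
        "cells_post_chemo": traj.cells_post_chemo,
        "cells_post_intervention": traj.cells_post_intervention,
        "relapse_clock_origin": "intervention_step",
    }


def _write_manifest(out: Path, cfg, seeds: list[int], files: list[str]) -> RunManifest:
    manifest = RunManifest(
        config_hash=config_hash(cfg),
        seeds=seeds,
        files=sorted(files),
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    return manifest


def export_trajectory(traj: Trajectory, out_dir: Union[str, Path]) -> RunManifest:
    """Write trajectory.csv, composition_long.csv, events.json and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(out / "trajectory.csv", index=False)
    traj.composition_frame().to_csv(out / "composition_long.csv", index=False)
    events = _events_dict(traj)
    events["config"] = config_to_dict(traj.config)
    with open(out / "events.json", "w") as fh:
        json.dump(events, fh, indent=2)
    files = ["trajectory.csv", "composition_long.csv", "events.json", "manifest.json"]
    return _write_manifest(out, traj.config, [traj.config.seed], files)


def export_cohort(summary: CohortSummary, out_dir: Union[str, Path]) -> RunManifest:
    """Write replicates.csv, summary.json and the manifest (plus trajectories
    in long form when the cohort kept them)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_frame().to_csv(out / "replicates.csv", index=False)
    payload = {
        "stats": summary.stats(),
        "seeds": summary.seeds,
        "config": config_to_dict(summary.spec),
        "relapse_mean_complete_case": _opt_mean(summary.relapse_times()),
        "relapse_mean_censored_floor": _opt_mean(summary.relapse_times(include_censored=True)),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    files = ["replicates.csv", "summary.json", "manifest.json"]
    if summary.trajectories is not None:
        frames = []
        for i, traj in enumerate(summary.trajectories):
            df = traj.to_frame()
            df.insert(0, "replicate", i)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "trajectories_long.csv", index=False
        )
        files.append("trajectories_long.csv")
    return _write_manifest(out, summary.spec, summary.seeds, files)


def export_comparison(
    a: CohortSummary, b: CohortSummary, out_dir: Union[str, Path]
) -> RunManifest:
    """Write the two-cohort comparison (stats plus t-tests) and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = compare_cohorts(a, b)
    result["config_a"] = config_to_dict(a.spec)
    result["config_b"] = config_to_dict(b.spec)
    with open(out / "comparison.json", "w") as fh:
        json.dump(result, fh, indent=2)
    return _write_manifest(
        out, a.spec, a.seeds + b.seeds, ["comparison.json", "manifest.json"]
    )


def _opt_mean(x) -> Optional[float]:
    return float(x.mean()) if getattr(x, "size", 0) else None
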