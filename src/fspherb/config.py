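"""Run-configuration documents (YAML/JSON) and output writers.

A configuration file is a mapping with optional sections ``run`` (density,
n_plants, duration_days, seeds), ``plant``, ``herbivore``, ``light``,
``weather`` and ``treatment``; every omitted key falls back to the packaged
default.  Unknown keys are rejected with the offending name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .engine import RunConfig, Treatment
from .params import (HerbivoreParameters, LightParameters, PlantParameters,
                     WeatherParameters)

_SECTIONS = {
    "plant": PlantParameters,
    "herbivore": HerbivoreParameters,
    "light": LightParameters,
    "weather": WeatherParameters,
    "treatment": Treatment,
}
_RUN_KEYS = {"density", "n_plants", "duration_days", "seed_plants",
             "seed_light", "seed_herbivores"}


def _build(cls, section: str, values: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - names
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid '{section}' configuration: {exc}") from exc


def config_from_dict(doc: dict | None) -> RunConfig:
    doc = dict(doc or {})
    unknown = set(doc) - set(_SECTIONS) - {"run"}
    if unknown:
        raise ValueError(f"unknown section(s): {sorted(unknown)}")
    run_doc = dict(doc.get("run") or {})
    bad = set(run_doc) - _RUN_KEYS
    if bad:
        raise ValueError(f"unknown key(s) in 'run': {sorted(bad)}")
    parts = {}
    for section, cls in _SECTIONS.items():
        parts[section] = _build(cls, section, dict(doc.get(section) or {}))
    return RunConfig(
        plant=parts["plant"], herbivore=parts["herbivore"],
        light=parts["light"], weather_params=parts["weather"],
        treatment=parts["treatment"], **run_doc)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("configuration root must be a mapping")
    return config_from_dict(doc)


def config_to_dict(cfg: RunConfig) -> dict:
    return {
        "run": {k: getattr(cfg, k) for k in sorted(_RUN_KEYS)},
        "plant": dataclasses.asdict(cfg.plant),
        "herbivore": dataclasses.asdict(cfg.herbivore),
        "light": dataclasses.asdict(cfg.light),
        "weather": dataclasses.asdict(cfg.weather_params),
        "treatment": dataclasses.asdict(cfg.treatment),
    }


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_outputs(result, out_dir, force: bool = False) -> dict:
    """Write run outputs as CSV plus a JSON metadata echo.

    Returns the mapping of logical name to written path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("plants", result.plants), ("daily", result.daily),
                     ("leaf_profile", result.leaf_profile),
                     ("herbivores", result.herbivores)):
        if df is None:
            continue
        target = out / f"{name}.csv"
        if target.exists() and not force:
            raise FileExistsError(f"{target} exists (use force=True)")
        df.to_csv(target, index=False, float_format="%.17g")
        paths[name] = target
    meta = {
        "seeds": result.config.seeds(),
        "config_hash": config_hash(result.config),
        "config": config_to_dict(result.config),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=float))
    paths["metadata"] = out / "metadata.json"
    return paths
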