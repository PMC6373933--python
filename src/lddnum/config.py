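"""Run configuration, YAML (de)serialization, and seed bookkeeping."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .observer import PopulationParams
from .stimulus import RegionGeometry, StimulusSpec

__all__ = [
    "RunConfig",
    "config_hash",
    "stimulus_spec_to_dict",
    "stimulus_spec_from_dict",
    "load_population",
    "save_population",
]


@dataclass(frozen=True)
class RunConfig:
    """One reproducible simulation/analysis run."""

    experiment: int = 1
    n_subjects: int = 55
    seed: int = 0
    population_file: Optional[str] = None
    out_dir: str = "results"
    export_frames: bool = False
    export_event_log: bool = True

    def population(self) -> PopulationParams:
        if self.population_file is None:
            return PopulationParams()
        return load_population(self.population_file)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def config_hash(cfg) -> str:
    """Short stable hash identifying a configuration (stamped on outputs)."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stimulus_spec_to_dict(spec: StimulusSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["region"] = {
        "centers": [list(c) for c in spec.region.centers],
        "sides": list(spec.region.sides),
        "rotation_rad": spec.region.rotation_rad,
    }
    if isinstance(spec.dot_diameter_deg, (tuple, list)):
        d["dot_diameter_deg"] = list(spec.dot_diameter_deg)
    d["color_labels"] = list(spec.color_labels)
    return d


def stimulus_spec_from_dict(d: dict) -> StimulusSpec:
    d = dict(d)
    reg = d.pop("region", None)
    region = (
        RegionGeometry(
            centers=tuple(tuple(c) for c in reg["centers"]),
            sides=tuple(reg["sides"]),
            rotation_rad=float(reg.get("rotation_rad", 0.0)),
        )
        if reg
        else RegionGeometry.single_square()
    )
    dd = d.get("dot_diameter_deg")
    if isinstance(dd, list):
        d["dot_diameter_deg"] = tuple(dd)
    if "color_labels" in d:
        d["color_labels"] = tuple(d["color_labels"])
    return StimulusSpec(region=region, **d)


def load_population(path: str | Path) -> PopulationParams:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PopulationParams.from_dict(raw)


def save_population(pop: PopulationParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(pop.to_dict(), sort_keys=False))
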