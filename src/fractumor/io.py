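"""YAML/CSV/JSON serialization: parameter sets, profiles, protocols, runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import PatientProfile, TreatmentProtocol
from .dosing import DoseSchedule, HyperthermiaSession
from .parameters import PARAMETER_CATEGORIES, PARAMETER_NAMES, ModelParameters
from .solver import SimulationConfig, SimulationResult
from .state import STATE_NAMES


def bundled_path(*parts: str) -> Path:
    """Path to a bundled data file, e.g. ``bundled_path('baseline.yaml')``."""
    return Path(__file__).parent / "data" / Path(*parts)


def params_to_yaml(params: ModelParameters, path) -> None:
    """Write a flat key -> value file with a category sidecar block."""
    doc = {
        "parameters": {n: float(getattr(params, n)) for n in PARAMETER_NAMES},
        "category": dict(PARAMETER_CATEGORIES),
        "circadian_enabled": bool(params.circadian_enabled),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def params_from_yaml(path) -> ModelParameters:
    doc = yaml.safe_load(Path(path).read_text())
    values = doc["parameters"] if "parameters" in doc else doc
    kwargs = {n: float(values[n]) for n in PARAMETER_NAMES}
    kwargs["circadian_enabled"] = bool(doc.get("circadian_enabled", True))
    return ModelParameters(**kwargs)


def profile_to_yaml(profile: PatientProfile, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(profile), sort_keys=False))


def profile_from_yaml(path) -> PatientProfile:
    return PatientProfile(**yaml.safe_load(Path(path).read_text()))


def protocol_to_yaml(protocol: TreatmentProtocol, path) -> None:
    doc = {
        "name": protocol.name,
        "schedules": [asdict(s) for s in protocol.schedules],
        "hyperthermia": asdict(protocol.hyperthermia) if protocol.hyperthermia else None,
        "resistance_parameter": protocol.resistance_parameter,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def protocol_from_yaml(path) -> TreatmentProtocol:
    doc = yaml.safe_load(Path(path).read_text())
    return TreatmentProtocol(
        name=doc["name"],
        schedules=[DoseSchedule(**s) for s in doc["schedules"]],
        hyperthermia=HyperthermiaSession(**doc["hyperthermia"]) if doc.get("hyperthermia") else None,
        resistance_parameter=doc.get("resistance_parameter"),
    )


def parameter_hash(params: ModelParameters) -> str:
    payload = json.dumps(
        {n: float(getattr(params, n)) for n in PARAMETER_NAMES}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def trajectory_to_csv(result: SimulationResult, path) -> None:
    """Tidy CSV: time, the 15 state names, per-drug dose, temperature."""
    df = pd.DataFrame(result.states, columns=list(STATE_NAMES))
    df.insert(0, "time", result.times)
    for drug, conc in result.drug_concentrations.items():
        df[f"conc_{drug}"] = conc
    for drug, dose in result.doses.items():
        df[f"dose_{drug}"] = dose
    df["temperature"] = result.temperature
    df.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Machine-readable record of one simulation or analysis run."""

    artifact_version: str
    parameter_hash: str
    config: Dict[str, object]
    solver: Dict[str, object]
    wall_time_s: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def make_manifest(
    params: ModelParameters,
    config: SimulationConfig,
    result: Optional[SimulationResult] = None,
    wall_time_s: Optional[float] = None,
) -> RunManifest:
    from . import __version__

    cfg = dataclasses.asdict(config)
    cfg["method_chain"] = list(cfg["method_chain"])
    solver_info: Dict[str, object] = {}
    if result is not None:
        solver_info = {
            "method_used": result.method_used,
            "fallback_level": result.fallback_level,
            "converged": bool(result.converged),
            "is_dummy": bool(result.is_dummy),
        }
    return RunManifest(
        artifact_version=__version__,
        parameter_hash=parameter_hash(params),
        config=cfg,
        solver=solver_info,
        wall_time_s=wall_time_s,
    )
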