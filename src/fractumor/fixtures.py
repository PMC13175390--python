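"""Seeded fixture generation: parameter files and short reference trajectories.

Everything any test or example needs is generated programmatically:
(a) the bundled baseline parameter file, (b) randomized-but-valid
parameter sets for property tests, and (c) short reference trajectories
computed by the fixed-step integrator for oracle comparison.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np

from .cohort import PROFILE_NAMES, PROTOCOL_NAMES, make_patient_profile, make_protocol
from .io import params_to_yaml, profile_to_yaml, protocol_to_yaml, trajectory_to_csv
from .parameters import PARAMETER_NAMES, ModelParameters, baseline_parameters
from .solver import SimulationConfig, reference_integrate

#: parameters that must stay inside an open unit-type interval when jittered
_BOUNDED = {"hypoxia_threshold": (0.05, 0.95), "bioavailability": (0.05, 1.0),
            "circadian_amplitude": (0.0, 0.95)}


def random_parameters(rng: np.random.Generator, spread: float = 0.2) -> ModelParameters:
    """A valid parameter set with each value jittered around baseline."""
    base = baseline_parameters()
    kwargs = {}
    for name in PARAMETER_NAMES:
        value = getattr(base, name) * rng.uniform(1.0 - spread, 1.0 + spread)
        if name in _BOUNDED:
            lo, hi = _BOUNDED[name]
            value = float(np.clip(value, lo, hi))
        if name == "circadian_phase":
            value = float(rng.uniform(0.0, 1.0))
        kwargs[name] = value
    return ModelParameters(**kwargs)


def make_fixtures(seed: int, outdir, n_random: int = 5, horizon_days: float = 10.0) -> List[Path]:
    """Write the fixture set under ``outdir``; byte-identical for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: List[Path] = []

    base = baseline_parameters()
    path = outdir / "baseline.yaml"
    params_to_yaml(base, path)
    written.append(path)

    for i in range(n_random):
        path = outdir / f"random_params_{i}.yaml"
        params_to_yaml(random_parameters(rng), path)
        written.append(path)

    for name in PROFILE_NAMES:
        path = outdir / f"profile_{name}.yaml"
        profile_to_yaml(make_patient_profile(name), path)
        written.append(path)
    for name in PROTOCOL_NAMES:
        path = outdir / f"protocol_{name}.yaml"
        protocol_to_yaml(make_protocol(name), path)
        written.append(path)

    config = SimulationConfig(duration=horizon_days, n_points=int(horizon_days) + 1)
    for protocol_name in ("standard", "continuous"):
        result = reference_integrate(config, base, make_protocol(protocol_name), dt=0.01)
        path = outdir / f"reference_{protocol_name}_{int(horizon_days)}d.csv"
        trajectory_to_csv(result, path)
        written.append(path)
    return written
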