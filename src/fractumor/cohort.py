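"""Virtual patient profiles and named treatment protocols.

Four discrete patient profiles (average, young, elderly, compromised)
modify the baseline parameters: mutation rate and genetic instability are
replaced, liver/kidney function enter the adjusted drug elimination rate,
and immune status scales the immune production rates phi1 and phi2.  The
remaining demographic factors (age, performance status) are stored for
reporting but are deliberately inert in the dynamics.

Five treatment protocols are bundled:

========================  =====================================================
standard                  hormone + HER2, cyclic 14 d on / 7 d off, dose 0.8
continuous                hormone + HER2, constant dose 0.8
adaptive                  hormone + HER2, response-guided dose in [0.6, 0.9]
immuno_combo              chemo 7/14 at 0.6 plus immunotherapy 2/19 at 0.7
hyperthermia              hormone + HER2 cyclic 14/7 at 0.7 plus 38.5 degC
                          sessions, 2 days every 21
========================  =====================================================

The continuous and adaptive protocols carry a resistance-development
multiplier (sustained selection pressure accelerates resistance under
continuous dosing, adaptive dosing slows it); it is resolved from the
parameter set at simulation time so that perturbing those parameters
propagates to outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .dosing import DoseSchedule, HyperthermiaSession
from .parameters import ModelParameters

PROFILE_NAMES = ("average", "young", "elderly", "compromised")
PROTOCOL_NAMES = ("standard", "continuous", "adaptive", "immuno_combo", "hyperthermia")

#: default initial dose for the adaptive protocol: midpoint of its dose band
ADAPTIVE_INITIAL_DOSE = 0.75


@dataclass(frozen=True)
class PatientProfile:
    """Parameter modifications defining one virtual patient population."""

    name: str
    age_factor: float
    performance_status: float
    immune_status: float
    liver_function: float
    kidney_function: float
    mutation_rate: float
    genetic_instability: float


_PROFILE_TABLE: Dict[str, PatientProfile] = {
    "average": PatientProfile("average", 1.0, 1.0, 1.0, 1.0, 1.0, 0.0001, 1.0),
    "young": PatientProfile("young", 1.2, 1.2, 1.3, 1.1, 1.1, 0.00008, 1.0),
    "elderly": PatientProfile("elderly", 0.8, 0.8, 0.7, 0.9, 0.85, 0.00015, 1.0),
    "compromised": PatientProfile("compromised", 0.8, 0.7, 0.6, 0.7, 0.7, 0.00015, 1.2),
}


@dataclass
class TreatmentProtocol:
    """A named drug-schedule bundle plus optional hyperthermia sessions."""

    name: str
    schedules: List[DoseSchedule] = field(default_factory=list)
    hyperthermia: Optional[HyperthermiaSession] = None
    #: parameter name holding the resistance-development multiplier, if any
    resistance_parameter: Optional[str] = None

    def resistance_multiplier(self, params: ModelParameters) -> float:
        if self.resistance_parameter is None:
            return 1.0
        return getattr(params, self.resistance_parameter)

    @property
    def is_adaptive(self) -> bool:
        return any(s.kind == "adaptive" for s in self.schedules)


def make_patient_profile(name: str) -> PatientProfile:
    """Look up one of the four named patient profiles."""
    try:
        return _PROFILE_TABLE[name]
    except KeyError:
        raise KeyError(f"unknown patient profile {name!r}; choose from {PROFILE_NAMES}") from None


def apply_profile(baseline: ModelParameters, profile: PatientProfile) -> ModelParameters:
    """Return a new parameter set with the profile's modifications applied.

    The baseline is never mutated.  Immune status scales phi1 and phi2
    (immune production); liver/kidney function feed the adjusted
    elimination rate; mutation rate and genetic instability are replaced.
    """
    return baseline.replace(
        mutation_rate=profile.mutation_rate,
        genetic_instability=profile.genetic_instability,
        liver_function=profile.liver_function,
        kidney_function=profile.kidney_function,
        immune_status=profile.immune_status,
        age_factor=profile.age_factor,
        performance_status=profile.performance_status,
        phi1=baseline.phi1 * profile.immune_status,
        phi2=baseline.phi2 * profile.immune_status,
    )


def make_protocol(name: str, profile: Optional[PatientProfile] = None) -> TreatmentProtocol:
    """Build one of the five named treatment protocols.

    ``profile`` is accepted for interface symmetry with profile-aware
    protocol construction; the bundled protocols do not vary by patient.
    """
    if name == "standard":
        return TreatmentProtocol(
            name=name,
            schedules=[
                DoseSchedule(drug_type="hormone", kind="cyclic", dose=0.8,
                             treatment_days=14, rest_days=7),
                DoseSchedule(drug_type="her2", kind="cyclic", dose=0.8,
                             treatment_days=14, rest_days=7),
            ],
        )
    if name == "continuous":
        return TreatmentProtocol(
            name=name,
            schedules=[
                DoseSchedule(drug_type="hormone", kind="continuous", dose=0.8),
                DoseSchedule(drug_type="her2", kind="continuous", dose=0.8),
            ],
            resistance_parameter="continuous_resist_dev",
        )
    if name == "adaptive":
        adaptive = dict(kind="adaptive", dose=ADAPTIVE_INITIAL_DOSE,
                        min_dose=0.6, max_dose=0.9, monitoring_period=21,
                        target_ratio=1.0, step=0.1)
        return TreatmentProtocol(
            name=name,
            schedules=[
                DoseSchedule(drug_type="hormone", **adaptive),
                DoseSchedule(drug_type="her2", **adaptive),
            ],
            resistance_parameter="adaptive_resist_dev",
        )
    if name == "immuno_combo":
        return TreatmentProtocol(
            name=name,
            schedules=[
                DoseSchedule(drug_type="chemo", kind="cyclic", dose=0.6,
                             treatment_days=7, rest_days=14),
                DoseSchedule(drug_type="immuno", kind="cyclic", dose=0.7,
                             treatment_days=2, rest_days=19),
            ],
        )
    if name == "hyperthermia":
        return TreatmentProtocol(
            name=name,
            schedules=[
                DoseSchedule(drug_type="hormone", kind="cyclic", dose=0.7,
                             treatment_days=14, rest_days=7),
                DoseSchedule(drug_type="her2", kind="cyclic", dose=0.7,
                             treatment_days=14, rest_days=7),
            ],
            hyperthermia=HyperthermiaSession(temperature=38.5, duration_days=2,
                                             period_days=21),
        )
    raise KeyError(f"unknown protocol {name!r}; choose from {PROTOCOL_NAMES}")
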