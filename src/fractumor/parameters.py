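"""Model parameters with evidence-category metadata.

The model has 58 named parameters grouped by the strength of their
evidential basis: ``experimental`` (11, direct laboratory measurements),
``clinical`` (21, guidelines and pharmacokinetic studies), ``literature``
(19, values adopted from published mathematical models) and
``hypothetical`` (7, plausibility-based settings without direct
measurement).  Rates are per day; the circadian period is stored in days
(24 h == 1.0 d).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Iterator, Tuple


class ParameterError(ValueError):
    """Raised when a parameter set fails validation."""


#: parameter name -> evidence category for the full 58-parameter set
PARAMETER_CATEGORIES: Dict[str, str] = {
    # experimental (n = 11)
    "lambda1": "experimental",
    "lambda2": "experimental",
    "beta1": "experimental",
    "omega_r1": "experimental",
    "omega_r2": "experimental",
    "mutation_rate": "experimental",
    "metabolic_switch_rate": "experimental",
    "hypoxia_threshold": "experimental",
    "circadian_amplitude": "experimental",
    "circadian_period": "experimental",
    "circadian_phase": "experimental",
    # clinical (n = 21)
    "absorption_rate": "clinical",
    "elimination_rate": "clinical",
    "bioavailability": "clinical",
    "ec50": "clinical",
    "hill_coef": "clinical",
    "max_drug_effect": "clinical",
    "distribution_vol": "clinical",
    "eta_e": "clinical",
    "eta_h": "clinical",
    "eta_c": "clinical",
    "treatment_cycle_period": "clinical",
    "treatment_active_days": "clinical",
    "rest_period_days": "clinical",
    "treatment_intensity": "clinical",
    "age_factor": "clinical",
    "performance_status": "clinical",
    "bmi_factor": "clinical",
    "immune_status": "clinical",
    "liver_function": "clinical",
    "kidney_function": "clinical",
    "prior_treatment_factor": "clinical",
    # literature (n = 19)
    "carrying_capacity": "literature",
    "phi1": "literature",
    "phi2": "literature",
    "phi3": "literature",
    "beta2": "literature",
    "delta_i": "literature",
    "lambda_r1": "literature",
    "lambda_r2": "literature",
    "gamma_met": "literature",
    "delta_p": "literature",
    "alpha_a": "literature",
    "delta_a": "literature",
    "kappa_q": "literature",
    "lambda_q": "literature",
    "kappa_s": "literature",
    "delta_s": "literature",
    "epigenetic_silencing": "literature",
    "genetic_instability": "literature",
    "acidosis_factor": "literature",
    # hypothetical (n = 7)
    "immune_resist_factor1": "hypothetical",
    "immune_resist_factor2": "hypothetical",
    "continuous_resist_dev": "hypothetical",
    "adaptive_resist_dev": "hypothetical",
    "immuno_resist_boost": "hypothetical",
    "resistance_floor": "hypothetical",
    "microenv_stress_factor": "hypothetical",
}

#: functional grouping used when aggregating sensitivity results
PARAMETER_GROUPS: Dict[str, str] = {
    "lambda1": "growth", "lambda2": "growth", "lambda_r1": "growth",
    "lambda_r2": "growth", "carrying_capacity": "growth",
    "acidosis_factor": "growth",
    "beta1": "immune", "beta2": "immune", "phi1": "immune", "phi2": "immune",
    "phi3": "immune", "delta_i": "immune",
    "immune_resist_factor1": "immune", "immune_resist_factor2": "immune",
    "omega_r1": "resistance", "omega_r2": "resistance",
    "continuous_resist_dev": "resistance", "adaptive_resist_dev": "resistance",
    "immuno_resist_boost": "resistance", "resistance_floor": "resistance",
    "kappa_q": "dormancy", "lambda_q": "dormancy", "kappa_s": "dormancy",
    "delta_s": "dormancy",
    "hypoxia_threshold": "microenvironment",
    "metabolic_switch_rate": "microenvironment",
    "microenv_stress_factor": "microenvironment",
    "gamma_met": "metastasis", "delta_p": "metastasis",
    "alpha_a": "angiogenesis", "delta_a": "angiogenesis",
    "mutation_rate": "genetics", "genetic_instability": "genetics",
    "epigenetic_silencing": "genetics",
    "absorption_rate": "pharmacokinetics", "elimination_rate": "pharmacokinetics",
    "bioavailability": "pharmacokinetics", "ec50": "pharmacokinetics",
    "hill_coef": "pharmacokinetics", "max_drug_effect": "pharmacokinetics",
    "distribution_vol": "pharmacokinetics",
    "eta_e": "treatment_efficacy", "eta_h": "treatment_efficacy",
    "eta_c": "treatment_efficacy",
    "treatment_cycle_period": "treatment_scheduling",
    "treatment_active_days": "treatment_scheduling",
    "rest_period_days": "treatment_scheduling",
    "treatment_intensity": "treatment_scheduling",
    "circadian_amplitude": "circadian", "circadian_period": "circadian",
    "circadian_phase": "circadian",
    "age_factor": "patient", "performance_status": "patient",
    "bmi_factor": "patient", "immune_status": "patient",
    "liver_function": "patient", "kidney_function": "patient",
    "prior_treatment_factor": "patient",
}

PARAMETER_NAMES: Tuple[str, ...] = tuple(PARAMETER_CATEGORIES)


@dataclass
class ModelParameters:
    """The 58 named model parameters at their baseline values.

    ``circadian_enabled`` is a switch, not a counted parameter.  Parameters
    that appear in the tables but in no printed flux (``epigenetic_silencing``,
    ``bmi_factor``, ``age_factor``, ``performance_status``,
    ``prior_treatment_factor``, ``microenv_stress_factor``) are stored and
    validated but deliberately inert in the dynamics.
    """

    # growth
    lambda1: float = 0.003          # sensitive tumor growth rate, 1/d
    lambda2: float = 0.002          # partially resistant growth rate, 1/d
    lambda_r1: float = 0.006        # type-1 resistant growth rate, 1/d
    lambda_r2: float = 0.005        # type-2 resistant growth rate, 1/d
    carrying_capacity: float = 1000.0
    acidosis_factor: float = 0.01
    # immune
    beta1: float = 0.005            # cytotoxic killing rate, 1/d
    beta2: float = 0.001            # regulatory suppression rate, 1/d
    phi1: float = 0.1               # baseline immune production, 1/d
    phi2: float = 0.001             # tumor-driven immune recruitment
    phi3: float = 0.0003            # regulatory immune recruitment
    delta_i: float = 0.04           # immune death rate, 1/d
    immune_resist_factor1: float = 0.10
    immune_resist_factor2: float = 0.05
    # resistance
    omega_r1: float = 0.004
    omega_r2: float = 0.003
    continuous_resist_dev: float = 2.0
    adaptive_resist_dev: float = 1.2
    immuno_resist_boost: float = 0.5
    resistance_floor: float = 0.01
    # dormancy
    kappa_q: float = 0.001          # quiescence entry, 1/d
    lambda_q: float = 0.0005        # quiescence exit, 1/d
    kappa_s: float = 0.0005         # senescence induction, 1/d
    delta_s: float = 0.005          # senescence clearance, 1/d
    # microenvironment
    hypoxia_threshold: float = 0.3
    metabolic_switch_rate: float = 0.02
    microenv_stress_factor: float = 1.0
    # metastasis / angiogenesis
    gamma_met: float = 0.0001
    delta_p: float = 0.01
    alpha_a: float = 0.01
    delta_a: float = 0.1
    # genetics
    mutation_rate: float = 0.0001
    genetic_instability: float = 1.0
    epigenetic_silencing: float = 0.002
    # pharmacokinetics
    absorption_rate: float = 0.5
    elimination_rate: float = 0.1
    bioavailability: float = 0.85
    ec50: float = 0.3
    hill_coef: float = 1.5
    max_drug_effect: float = 1.0
    distribution_vol: float = 70.0
    # treatment efficacy coefficients
    eta_e: float = 0.01
    eta_h: float = 0.01
    eta_c: float = 0.01
    # scheduling defaults
    treatment_cycle_period: float = 21.0
    treatment_active_days: float = 7.0
    rest_period_days: float = 14.0
    treatment_intensity: float = 1.0
    # circadian (period stored in days; 24 h == 1.0 d)
    circadian_amplitude: float = 0.2
    circadian_period: float = 1.0
    circadian_phase: float = 0.0
    # patient factors
    age_factor: float = 1.0
    performance_status: float = 1.0
    bmi_factor: float = 1.0
    immune_status: float = 1.0
    liver_function: float = 1.0
    kidney_function: float = 1.0
    prior_treatment_factor: float = 1.0
    # switch, not a counted parameter
    circadian_enabled: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if name == "circadian_phase":
                continue  # a phase offset; zero and negatives are meaningful
            if not value > 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        if not 0 < self.hypoxia_threshold < 1:
            raise ParameterError("hypoxia_threshold must lie in (0, 1)")
        if not 0 < self.bioavailability <= 1:
            raise ParameterError("bioavailability must lie in (0, 1]")
        if self.circadian_amplitude >= 1:
            raise ParameterError(
                "circadian_amplitude >= 1 would allow nonpositive modulated rates"
            )

    # -- dict-style access -------------------------------------------------
    def copy(self) -> "ModelParameters":
        return dataclasses.replace(self)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def __getitem__(self, name: str) -> float:
        if name not in PARAMETER_CATEGORIES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self) -> Iterator[Tuple[str, float]]:
        return ((n, getattr(self, n)) for n in PARAMETER_NAMES)

    def to_dict(self) -> Dict[str, float]:
        return {n: getattr(self, n) for n in PARAMETER_NAMES}

    def category(self, name: str) -> str:
        return PARAMETER_CATEGORIES[name]

    def adjusted_elimination(self) -> float:
        """Clearance rate adjusted for organ function."""
        return self.elimination_rate * self.liver_function * self.kidney_function


def baseline_parameters() -> ModelParameters:
    """The bundled baseline parameter set (all table values)."""
    return ModelParameters()


def category_counts(params: ModelParameters | None = None) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for cat in PARAMETER_CATEGORIES.values():
        counts[cat] = counts.get(cat, 0) + 1
    return counts
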