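"""Dosing schedules, pharmacokinetic input and Hill-equation drug effects.

Four drug types are modelled: ``hormone`` (endocrine therapy), ``her2``
(HER2-targeted therapy), ``chemo`` (chemotherapy) and ``immuno``
(immunotherapy).  Each drug gets its own concentration compartment; the
state's aggregate ``D`` equals their sum.  Scheduled doses are converted
to an absorption flux (dose x bioavailability / distribution volume x
absorption rate) and concentrations are cleared at the organ-function
adjusted elimination rate.  Drug effect on the dynamics is the Hill
transform of the concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

from .parameters import ModelParameters, ParameterError

DRUG_TYPES = ("hormone", "her2", "chemo", "immuno")


class SchedulingError(ValueError):
    """Raised when a schedule cannot be evaluated."""


@dataclass
class DoseSchedule:
    """Per-drug time -> dose rule.

    ``kind`` is one of ``cyclic`` (treatment_days on / rest_days off),
    ``continuous`` (constant dose) or ``adaptive`` (response-guided dose
    within [min_dose, max_dose], re-evaluated every ``monitoring_period``
    days).  ``dose`` is the nominal (for adaptive: initial) dose.
    """

    drug_type: str = "hormone"
    kind: str = "cyclic"
    dose: float = 0.8
    treatment_days: float = 14.0
    rest_days: float = 7.0
    start_day: float = 0.0
    monitoring_period: float = 21.0
    target_ratio: float = 1.0
    min_dose: float = 0.6
    max_dose: float = 0.9
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.drug_type not in DRUG_TYPES:
            raise ParameterError(f"unknown drug_type {self.drug_type!r}")
        if self.kind not in ("cyclic", "continuous", "adaptive"):
            raise ParameterError(f"unknown schedule kind {self.kind!r}")
        if self.dose < 0:
            raise ParameterError("dose must be nonnegative")
        if self.treatment_days < 0 or self.rest_days < 0:
            raise ParameterError("treatment_days and rest_days must be nonnegative")
        if self.kind == "cyclic" and self.treatment_days + self.rest_days <= 0:
            raise ParameterError("cyclic schedule needs treatment_days + rest_days > 0")
        if self.kind == "adaptive" and not (self.min_dose <= self.dose <= self.max_dose):
            raise ParameterError("adaptive initial dose must lie within [min_dose, max_dose]")


@dataclass
class HyperthermiaSession:
    """Periodic thermal-therapy sessions (temperature held for a few days per cycle)."""

    temperature: float = 38.5
    duration_days: float = 2.0
    period_days: float = 21.0
    start_day: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature < 37.0:
            raise ParameterError("session temperature must be >= 37.0 degC")
        if self.duration_days > self.period_days:
            raise ParameterError("duration_days must not exceed period_days")

    def active(self, t: float) -> bool:
        if t < self.start_day:
            return False
        return (t - self.start_day) % self.period_days < self.duration_days


@dataclass
class DrugState:
    """Per-drug concentrations on board at one time point."""

    concentrations: Dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.concentrations.values())


def cyclic_dose(t: float, schedule: DoseSchedule) -> float:
    """Scheduled dose at time ``t`` for a cyclic or continuous schedule."""
    if t < schedule.start_day:
        return 0.0
    if schedule.kind == "continuous" or schedule.rest_days == 0:
        return schedule.dose
    period = schedule.treatment_days + schedule.rest_days
    if period <= 0:
        raise SchedulingError("zero cycle length")
    return schedule.dose if (t - schedule.start_day) % period < schedule.treatment_days else 0.0


def adaptive_dose(t: float, schedule: DoseSchedule, burden_history) -> float:
    """Replay the adaptive controller over ``burden_history`` up to time ``t``.

    ``burden_history`` is a pair of arrays ``(times, burdens)`` covering the
    controller's evaluation points.  The dose starts at ``schedule.dose`` and
    is re-evaluated at each monitoring boundary: if the burden ratio over the
    last monitoring period exceeds ``target_ratio`` the dose steps up, if it
    falls below ``1/target_ratio`` it steps down, otherwise it is held; the
    dose is always confined to ``[min_dose, max_dose]``.
    """
    times, burdens = burden_history
    times = list(times)
    if t >= schedule.start_day + schedule.monitoring_period and not times:
        raise SchedulingError("empty burden history at an adaptive evaluation boundary")
    dose = schedule.dose
    k = 1
    while schedule.start_day + k * schedule.monitoring_period <= t:
        boundary = schedule.start_day + k * schedule.monitoring_period
        now = _interp(boundary, times, burdens)
        prev = _interp(boundary - schedule.monitoring_period, times, burdens)
        dose = update_adaptive_dose(dose, now / prev, schedule)
        k += 1
    return dose


def update_adaptive_dose(dose: float, ratio: float, schedule: DoseSchedule) -> float:
    """One controller update given the burden ratio over a monitoring period."""
    if ratio > schedule.target_ratio:
        dose = min(dose + schedule.step, schedule.max_dose)
    elif ratio < 1.0 / schedule.target_ratio:
        dose = max(dose - schedule.step, schedule.min_dose)
    return dose


def _interp(t: float, times, values) -> float:
    if not times:
        raise SchedulingError("empty burden history")
    if t <= times[0]:
        return values[0]
    if t >= times[-1]:
        return values[-1]
    import numpy as np

    return float(np.interp(t, times, values))


def pk_input(
    t: float,
    schedules: Sequence[DoseSchedule],
    params: ModelParameters,
    dose_overrides: Optional[Dict[int, float]] = None,
) -> Dict[str, float]:
    """Per-drug absorption flux at time ``t``.

    The scheduled dose is scaled by ``treatment_intensity``, multiplied by
    bioavailability, converted to concentration units through the
    distribution volume, and absorbed at ``absorption_rate``.
    ``dose_overrides`` maps schedule index -> current dose and is how the
    solver injects the adaptive controller's state.
    """
    flux: Dict[str, float] = {}
    for i, sched in enumerate(schedules):
        if dose_overrides is not None and i in dose_overrides:
            dose = dose_overrides[i] if t >= sched.start_day else 0.0
        elif sched.kind == "adaptive":
            dose = sched.dose if t >= sched.start_day else 0.0
        else:
            dose = cyclic_dose(t, sched)
        if dose < 0:
            raise ParameterError("negative dose")
        effective = dose * params.treatment_intensity * params.bioavailability
        flux[sched.drug_type] = flux.get(sched.drug_type, 0.0) + (
            params.absorption_rate * effective / params.distribution_vol
        )
    return flux


def hill_effect(concentration: float, params: ModelParameters) -> float:
    """Sigmoidal dose-response: max_effect * c^h / (EC50^h + c^h)."""
    if params.ec50 <= 0:
        raise ParameterError("ec50 must be positive")
    if concentration <= 0:
        return 0.0
    ch = concentration ** params.hill_coef
    return params.max_drug_effect * ch / (params.ec50 ** params.hill_coef + ch)


def hyperthermia_modifier(temperature: float, theta_t: float = 0.1) -> float:
    """Multiplier on therapy_effect during thermal sessions: 1 + theta_t * excess degC."""
    return 1.0 + theta_t * max(0.0, temperature - 37.0)


def controls_at(
    t: float,
    drug_state: DrugState,
    params: ModelParameters,
    hyperthermia: Optional[HyperthermiaSession] = None,
    control_mode: str = "raw_dose",
    doses: Optional[Dict[str, float]] = None,
):
    """Map drugs on board to the model control inputs.

    With ``control_mode='raw_dose'`` (default) each control equals the
    currently scheduled dose of the matching drug scaled by
    ``treatment_intensity``; with ``'hill'`` it is the Hill transform of the
    drug's on-board concentration (a slower, saturating coupling through the
    pharmacokinetic compartment).  Temperature comes from an active
    hyperthermia session, and the immune-kill boost grows with the
    immunotherapy effect: ``immuno_boost = 1 + immuno_resist_boost * uI``.
    """
    from .model import ControlInputs

    conc = drug_state.concentrations
    doses = doses or {}

    def effect(drug: str) -> float:
        if control_mode == "raw_dose":
            return doses.get(drug, 0.0) * params.treatment_intensity
        return hill_effect(conc.get(drug, 0.0), params)

    u_i = effect("immuno")
    temperature = 37.0
    if hyperthermia is not None and hyperthermia.active(t):
        temperature = hyperthermia.temperature
    return ControlInputs(
        uE=effect("hormone"),
        uH=effect("her2"),
        uC=effect("chemo"),
        uI=u_i,
        temperature=temperature,
        immuno_boost=1.0 + params.immuno_resist_boost * u_i,
    )
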