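"""Right-hand side of the 15-compartment tumor-immune treatment model.

The dynamics couple logistic tumor growth under a shared carrying
capacity, cytotoxic/regulatory immune interactions with hypoxia-impaired
killing, therapy-driven resistance development and senescence,
quiescence, angiogenesis, metastatic potential, drug mass transfer,
genetic-stability damage/recovery, metabolic shift and hypoxia.  The
entire derivative vector is multiplied by a time-dependent memory factor
``fractional_factor(t, alpha)`` that emulates the power-law decay of a
fractional-order derivative of order ``alpha``: ``alpha = 1`` is the
memoryless classical system, smaller alpha strengthens the influence of
history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dosing import hyperthermia_modifier
from .parameters import ModelParameters, ParameterError
from .state import STATE_FLOOR, as_state_array, _check_finite


class NumericalFailure(RuntimeError):
    """Raised when a derivative evaluation produces a non-finite term."""


@dataclass
class ControlInputs:
    """Therapy control inputs at one time point.

    uE/uH/uC/uI are the dimensionless endocrine, HER2, chemotherapy and
    immunotherapy effects; ``temperature`` is body/tumor temperature in
    degC; ``immuno_boost`` multiplies the immune kill terms (>= 1 while
    immunotherapy is on board).
    """

    uE: float = 0.0
    uH: float = 0.0
    uC: float = 0.0
    uI: float = 0.0
    temperature: float = 37.0
    immuno_boost: float = 1.0

    def __post_init__(self) -> None:
        if min(self.uE, self.uH, self.uC, self.uI) < 0:
            raise ParameterError("control effects must be nonnegative")
        if self.temperature < 36.0:
            raise ParameterError("temperature below physiological range")
        if self.immuno_boost < 0:
            raise ParameterError("immuno_boost must be nonnegative")


@dataclass
class Intermediates:
    """Shared algebraic quantities entering several fluxes."""

    total_tumor: float
    carrying_capacity_factor: float
    growth_factor: float
    acidosis_effect: float
    hypoxia_factor: float
    hypoxia_effect: float  # computed and logged; not wired into any flux
    immune_kill_factor: float
    quiescence_factor: float
    therapy_effect: float
    resistance_dev_factor: float
    genetic_damage_rate: float
    metabolic_shift: float


def total_tumor_burden(state) -> float:
    """Total tumor burden N1 + N2 + Q + R1 + R2 + S."""
    y = as_state_array(state)
    _check_finite(y)
    return float(y[0] + y[1] + y[6] + y[7] + y[8] + y[9])


def circadian_factor(t: float, params: ModelParameters) -> float:
    """Circadian modulation 1 + amplitude * sin(2*pi*(t/period - phase)).

    When enabled the factor multiplies the growth rates (lambda1, lambda2),
    immune death (delta_i) and immune killing (beta1); nothing else.
    """
    if not params.circadian_enabled:
        return 1.0
    if params.circadian_period <= 0:
        raise ParameterError("circadian_period must be positive")
    return 1.0 + params.circadian_amplitude * math.sin(
        2.0 * math.pi * (t / params.circadian_period - params.circadian_phase)
    )


def fractional_factor(t: float, alpha: float) -> float:
    """Memory scaling factor applied to the whole derivative vector.

    Returns 1.0 for t <= 0 and ``0.01 * (1 + (1 - alpha) * min(t^-alpha, 100))``
    for t > 0.  The power-law term ``t^-alpha`` emulates the decaying memory
    kernel of a fractional derivative; its weight ``1 - alpha`` vanishes in
    the classical case alpha = 1, and the cap at 100 prevents overflow near
    t = 0.
    """
    if not 0.0 < alpha <= 1.0:
        raise ParameterError(f"fractional order alpha must lie in (0, 1], got {alpha}")
    if t <= 0.0:
        return 1.0
    return 0.01 * (1.0 + (1.0 - alpha) * min(t ** (-alpha), 100.0))


def compute_intermediates(
    t: float,
    state,
    params: ModelParameters,
    controls: ControlInputs,
    theta_t: float = 0.1,
    floor: float = STATE_FLOOR,
) -> Intermediates:
    """Populate the shared algebraic terms from a (floored) state."""
    if params.carrying_capacity <= 0:
        raise ParameterError("carrying_capacity must be positive")
    y = np.maximum(as_state_array(state), floor)
    G = min(y[12], 1.0)
    A, M = y[5], y[13]
    total = float(y[0] + y[1] + y[6] + y[7] + y[8] + y[9])
    K = params.carrying_capacity

    ccf = max(0.0, 1.0 - total / K)
    growth_factor = ccf * (1.0 + 0.2 * M)
    acidosis = 1.0 + params.acidosis_factor * M * (total / K)
    thr = params.hypoxia_threshold
    hypoxia_factor = max(0.0, total / K - thr) / (1.0 - thr)
    hypoxia_effect = 1.0 + hypoxia_factor * A / (1.0 + A)
    immune_kill_factor = 1.0 / (1.0 + 0.5 * hypoxia_factor)
    quiescence_factor = 1.0 + 0.5 * hypoxia_factor
    therapy = (
        params.eta_e * controls.uE
        + params.eta_h * controls.uH
        + params.eta_c * controls.uC
    ) * hyperthermia_modifier(controls.temperature, theta_t)
    resistance_dev_factor = 1.0 + (1.0 - G)
    genetic_damage_rate = (
        params.mutation_rate
        * params.genetic_instability
        * (1.0 + therapy + 0.5 * hypoxia_factor)
    )
    metabolic_shift = M * hypoxia_factor * params.metabolic_switch_rate
    return Intermediates(
        total_tumor=total,
        carrying_capacity_factor=ccf,
        growth_factor=growth_factor,
        acidosis_effect=acidosis,
        hypoxia_factor=hypoxia_factor,
        hypoxia_effect=hypoxia_effect,
        immune_kill_factor=immune_kill_factor,
        quiescence_factor=quiescence_factor,
        therapy_effect=therapy,
        resistance_dev_factor=resistance_dev_factor,
        genetic_damage_rate=genetic_damage_rate,
        metabolic_shift=metabolic_shift,
    )


def derivatives(
    t: float,
    state,
    params: ModelParameters,
    controls: ControlInputs,
    alpha: float = 1.0,
    resistance_multiplier: float = 1.0,
    drug_input: float = 0.0,
    *,
    theta_t: float = 0.1,
    metastasis_hypoxia_mode: str = "divide",
    floor: float = STATE_FLOOR,
) -> np.ndarray:
    """Time derivative of the 15-compartment state.

    The incoming state is clamped to the nonnegativity floor (and G to 1)
    before any term is evaluated.  ``resistance_multiplier`` scales the
    resistance-development rates omega_r1/omega_r2 (protocol-specific
    selection pressure); ``drug_input`` is the total absorption flux feeding
    the aggregate drug compartment.  The returned vector is the raw
    right-hand side multiplied by ``fractional_factor(t, alpha)``.
    """
    y = np.maximum(as_state_array(state), floor)
    y[12] = min(y[12], 1.0)
    N1, N2, I1, I2, P, A, Q, R1, R2, S, D, Dm, G, M, H = y

    inter = compute_intermediates(t, y, params, controls, theta_t=theta_t, floor=floor)
    cf = circadian_factor(t, params)
    lam1 = params.lambda1 * cf
    lam2 = params.lambda2 * cf
    beta1 = params.beta1 * cf
    delta_i = params.delta_i * cf

    gf_over_acid = inter.growth_factor / inter.acidosis_effect
    growth_n1 = lam1 * N1 * gf_over_acid
    growth_n2 = lam2 * N2 * gf_over_acid
    growth_r1 = params.lambda_r1 * R1 * gf_over_acid
    growth_r2 = params.lambda_r2 * R2 * gf_over_acid

    sat = 1.0 + 0.01 * inter.total_tumor
    kill = beta1 * I1 * inter.immune_kill_factor / sat
    ik_n1 = kill * N1
    ik_n2 = kill * N2 * 0.5
    ik_r1 = kill * R1 * params.immune_resist_factor1
    ik_r2 = kill * R2 * params.immune_resist_factor2

    prod_i1 = params.phi1 + params.phi2 * inter.total_tumor / sat
    suppress_i1 = params.beta2 * I1 * I2 / (1.0 + I1)
    prod_i2 = params.phi3 * inter.total_tumor / sat

    therapy = inter.therapy_effect
    rdev_scale = therapy * N1 * inter.resistance_dev_factor * resistance_multiplier
    rdev_r1 = max(params.omega_r1 * rdev_scale, 0.0)
    rdev_r2 = max(params.omega_r2 * rdev_scale, 0.0)

    qi_n1 = params.kappa_q * N1 * inter.quiescence_factor
    qi_n2 = params.kappa_q * N2 * inter.quiescence_factor
    q_react = params.lambda_q * Q / inter.quiescence_factor
    senescence = params.kappa_s * therapy * N1 * (1.0 + 0.3 * (1.0 - G))

    boost = controls.immuno_boost
    if metastasis_hypoxia_mode == "divide":
        met_drive = params.gamma_met * inter.total_tumor / (1.0 + 0.5 * inter.hypoxia_factor)
    elif metastasis_hypoxia_mode == "multiply":
        met_drive = params.gamma_met * inter.total_tumor * (1.0 + 0.5 * inter.hypoxia_factor)
    else:
        raise ParameterError(f"unknown metastasis_hypoxia_mode {metastasis_hypoxia_mode!r}")

    adj_elim = params.adjusted_elimination()

    dydt = np.array([
        growth_n1 - ik_n1 * boost - therapy * N1 - qi_n1 - rdev_r1 - rdev_r2 - senescence,
        growth_n2 - ik_n2 * boost - 0.5 * therapy * N2 - qi_n2,
        prod_i1 - suppress_i1 - delta_i * I1 + 0.1 * controls.uI * I1,
        prod_i2 - delta_i * I2 - 0.1 * controls.uI * I2,
        met_drive - params.delta_p * P,
        params.alpha_a * inter.total_tumor / sat - params.delta_a * A,
        qi_n1 + qi_n2 - q_react,
        rdev_r1 + growth_r1 - ik_r1 * boost,
        rdev_r2 + growth_r2 - ik_r2 * boost,
        senescence - params.delta_s * S,
        drug_input - adj_elim * D,
        adj_elim * D,
        -inter.genetic_damage_rate * G + 0.001 * (1.0 - G),
        inter.metabolic_shift - 0.05 * M,
        0.1 * inter.hypoxia_factor - 0.1 * A * H,
    ])
    if not np.all(np.isfinite(dydt)):
        from .state import STATE_NAMES

        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(dydt))]
        raise NumericalFailure(f"non-finite derivative for {bad}")
    return dydt * fractional_factor(t, alpha)
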