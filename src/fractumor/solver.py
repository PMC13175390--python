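"""Robust integration of the treatment model over the simulation horizon.

``safe_solve`` integrates the 15-compartment system (augmented with one
concentration compartment per drug schedule) with a method fallback
chain: each method in the chain is tried at the configured tolerances and
then at progressively relaxed tolerances before moving to the next
method.  If every attempt fails the result is a flagged constant "dummy"
trajectory rather than an exception.  The nonnegativity floor is applied
inside the right-hand side at every derivative evaluation, so the ODE
stays well defined even when the integrator probes slightly negative
states.

Adaptive protocols are integrated piecewise: at every monitoring-period
boundary the burden ratio over the elapsed period is fed to the dose
controller, and integration resumes with the updated dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .cohort import TreatmentProtocol
from .dosing import DrugState, controls_at, cyclic_dose, update_adaptive_dose
from .model import NumericalFailure, derivatives, fractional_factor
from .parameters import ModelParameters, ParameterError
from .state import STATE_FLOOR, StateVector, as_state_array, initial_state


@dataclass
class SimulationConfig:
    """Numerical settings for one simulation run."""

    duration: float = 500.0
    n_points: int = 501
    alpha: float = 1.0
    rtol: float = 1e-4
    atol: float = 1e-7
    method_chain: Tuple[str, ...] = ("RK45", "BDF", "Radau", "DOP853")
    relax_levels: int = 2        # extra x10 tolerance relaxations per method
    t_start: float = 1e-9        # sidestep the memory-factor jump at t = 0
    max_step: float = 0.25       # days; resolves the daily circadian cycle
    floor: float = STATE_FLOOR
    theta_t: float = 0.1         # hyperthermia modifier, per degC
    metastasis_hypoxia_mode: str = "divide"
    control_mode: str = "raw_dose"
    seed: Optional[int] = None   # reserved; the dynamics are deterministic

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.n_points < 2:
            raise ParameterError("n_points must be at least 2")
        if self.rtol <= 0 or self.atol <= 0:
            raise ParameterError("tolerances must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ParameterError("alpha must lie in (0, 1]")


@dataclass
class SimulationResult:
    """Daily-grid trajectory plus solver diagnostics."""

    times: np.ndarray
    states: np.ndarray                       # (n_points, 15), floored
    drug_concentrations: Dict[str, np.ndarray]
    doses: Dict[str, np.ndarray]
    temperature: np.ndarray
    method_used: Optional[str]
    fallback_level: int
    converged: bool
    is_dummy: bool

    def state_at(self, index: int) -> StateVector:
        return StateVector.from_array(self.states[index])


def _schedule_dose(t: float, sched, override: Optional[float]) -> float:
    if override is not None:
        return override if t >= sched.start_day else 0.0
    if sched.kind == "adaptive":
        return sched.dose if t >= sched.start_day else 0.0
    return cyclic_dose(t, sched)


def build_rhs(
    config: SimulationConfig,
    params: ModelParameters,
    protocol: TreatmentProtocol,
    current_doses: Dict[int, float],
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side over the extended state [15 core, one conc per schedule].

    ``current_doses`` maps schedule index -> controller dose; mutating it
    between integration segments changes the adaptive dose.
    """
    schedules = protocol.schedules
    res_param = protocol.resistance_parameter
    res_mult = getattr(params, res_param) if res_param else 1.0
    adj_elim = params.adjusted_elimination()
    flux_coef = (
        params.absorption_rate * params.treatment_intensity * params.bioavailability
        / params.distribution_vol
    )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        y = np.maximum(y, config.floor)
        conc: Dict[str, float] = {}
        doses: Dict[str, float] = {}
        fluxes = np.empty(len(schedules))
        for i, sched in enumerate(schedules):
            c = y[15 + i]
            conc[sched.drug_type] = conc.get(sched.drug_type, 0.0) + c
            dose = _schedule_dose(t, sched, current_doses.get(i))
            doses[sched.drug_type] = doses.get(sched.drug_type, 0.0) + dose
            fluxes[i] = flux_coef * dose
        controls = controls_at(
            t, DrugState(conc), params,
            hyperthermia=protocol.hyperthermia,
            control_mode=config.control_mode,
            doses=doses,
        )
        core = derivatives(
            t, y[:15], params, controls,
            alpha=config.alpha,
            resistance_multiplier=res_mult,
            drug_input=float(fluxes.sum()),
            theta_t=config.theta_t,
            metastasis_hypoxia_mode=config.metastasis_hypoxia_mode,
            floor=config.floor,
        )
        gamma = fractional_factor(t, config.alpha)
        dconc = (fluxes - adj_elim * y[15:]) * gamma
        return np.concatenate([core, dconc])

    return rhs


def _segments(config: SimulationConfig, protocol: TreatmentProtocol) -> List[float]:
    """Integration breakpoints: t=0, adaptive monitoring boundaries, horizon."""
    bounds = {0.0, float(config.duration)}
    for sched in protocol.schedules:
        if sched.kind != "adaptive":
            continue
        k = 1
        while sched.start_day + k * sched.monitoring_period < config.duration:
            bounds.add(sched.start_day + k * sched.monitoring_period)
            k += 1
    return sorted(bounds)


def _burden(y: np.ndarray) -> float:
    return float(y[0] + y[1] + y[6] + y[7] + y[8] + y[9])


def _try_segment(rhs, t0, t1, y0, t_eval, config):
    """Run one segment through the method/tolerance fallback ladder."""
    level = 0
    for method in config.method_chain:
        for relax in range(config.relax_levels + 1):
            try:
                sol = solve_ivp(
                    rhs, (t0, t1), y0,
                    method=method,
                    t_eval=t_eval if len(t_eval) else None,
                    rtol=config.rtol * 10 ** relax,
                    atol=config.atol * 10 ** relax,
                    max_step=config.max_step,
                )
            except (NumericalFailure, ValueError, FloatingPointError, OverflowError):
                sol = None
            if sol is not None and sol.success and np.all(np.isfinite(sol.y)):
                ys = sol.y.T if len(t_eval) else np.empty((0, len(y0)))
                yT = sol.y[:, -1] if sol.y.shape[1] else y0
                # solve_ivp with t_eval does not return the endpoint unless
                # it is in t_eval; integrate the tail if needed
                if len(t_eval) == 0 or not math.isclose(t_eval[-1], t1):
                    tail = solve_ivp(
                        rhs, (t_eval[-1] if len(t_eval) else t0, t1),
                        ys[-1] if len(t_eval) else y0,
                        method=method,
                        rtol=config.rtol * 10 ** relax,
                        atol=config.atol * 10 ** relax,
                        max_step=config.max_step,
                    )
                    if not tail.success:
                        level += 1
                        continue
                    yT = tail.y[:, -1]
                return ys, yT, method, level
            level += 1
    return None


def _dummy_result(config, grid, y0_core, schedules) -> SimulationResult:
    states = np.tile(np.maximum(y0_core, config.floor), (len(grid), 1))
    zeros = np.zeros(len(grid))
    return SimulationResult(
        times=grid,
        states=states,
        drug_concentrations={s.drug_type: zeros.copy() for s in schedules},
        doses={s.drug_type: zeros.copy() for s in schedules},
        temperature=np.full(len(grid), 37.0),
        method_used=None,
        fallback_level=len(config.method_chain) * (config.relax_levels + 1),
        converged=False,
        is_dummy=True,
    )


def safe_solve(
    config: SimulationConfig,
    params: ModelParameters,
    protocol: TreatmentProtocol,
    initial: Optional[StateVector] = None,
) -> SimulationResult:
    """Integrate the model over the horizon, never raising on numerical failure."""
    y0_core = as_state_array(initial if initial is not None else initial_state())
    # pre-existing resistant subclones: clamp R1/R2 up to the resistance floor
    y0_core[7] = max(y0_core[7], params.resistance_floor)
    y0_core[8] = max(y0_core[8], params.resistance_floor)

    schedules = protocol.schedules
    grid = np.linspace(0.0, config.duration, config.n_points)
    current_doses: Dict[int, float] = {
        i: s.dose for i, s in enumerate(schedules) if s.kind == "adaptive"
    }
    rhs = build_rhs(config, params, protocol, current_doses)

    y = np.concatenate([y0_core, np.zeros(len(schedules))])
    sample_t: List[float] = [0.0]
    sample_y: List[np.ndarray] = [y.copy()]
    dose_events: List[Tuple[float, Dict[int, float]]] = [(0.0, dict(current_doses))]

    method_used = None
    max_level = 0
    bounds = _segments(config, protocol)
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        seg_start = max(t0, config.t_start)
        t_eval = grid[(grid > t0 + 1e-12) & (grid <= t1 + 1e-12)]
        out = _try_segment(rhs, seg_start, t1, y, t_eval, config)
        if out is None:
            return _dummy_result(config, grid, y0_core, schedules)
        ys, y, method_used, level = out
        max_level = max(max_level, level)
        sample_t.extend(t_eval.tolist())
        sample_y.extend(list(ys))
        if current_doses and t1 < config.duration:
            # controller event: burden ratio over the elapsed monitoring period
            times_arr = np.array(sample_t)
            burdens = np.array([_burden(np.maximum(s, config.floor)) for s in sample_y])
            for i, sched in enumerate(schedules):
                if sched.kind != "adaptive":
                    continue
                now = _burden(np.maximum(y, config.floor))
                prev = float(np.interp(t1 - sched.monitoring_period, times_arr, burdens))
                current_doses[i] = update_adaptive_dose(
                    current_doses[i], now / prev, sched
                )
            dose_events.append((t1, dict(current_doses)))

    full = np.vstack(sample_y)
    times = np.array(sample_t)
    order = np.argsort(times)
    times, full = times[order], full[order]
    if len(times) != len(grid) or not np.allclose(times, grid):
        # align to the requested grid (guards against duplicated boundaries)
        keep = np.searchsorted(times, grid)
        keep = np.clip(keep, 0, len(times) - 1)
        full = full[keep]
        times = grid

    states = np.maximum(full[:, :15], config.floor)
    conc: Dict[str, np.ndarray] = {}
    for i, sched in enumerate(schedules):
        c = np.maximum(full[:, 15 + i], 0.0)
        conc[sched.drug_type] = conc.get(sched.drug_type, 0.0) + c

    doses: Dict[str, np.ndarray] = {s.drug_type: np.zeros(len(grid)) for s in schedules}
    for i, sched in enumerate(schedules):
        trace = np.empty(len(grid))
        for j, t in enumerate(grid):
            if sched.kind == "adaptive":
                d = sched.dose
                for t_ev, dd in dose_events:
                    if t >= t_ev:
                        d = dd[i]
                trace[j] = d if t >= sched.start_day else 0.0
            else:
                trace[j] = cyclic_dose(t, sched)
        doses[sched.drug_type] = doses[sched.drug_type] + trace

    temp = np.full(len(grid), 37.0)
    if protocol.hyperthermia is not None:
        temp = np.array([
            protocol.hyperthermia.temperature if protocol.hyperthermia.active(t) else 37.0
            for t in grid
        ])

    return SimulationResult(
        times=grid,
        states=states,
        drug_concentrations=conc,
        doses=doses,
        temperature=temp,
        method_used=method_used,
        fallback_level=max_level,
        converged=True,
        is_dummy=False,
    )


def reference_integrate(
    config: SimulationConfig,
    params: ModelParameters,
    protocol: TreatmentProtocol,
    initial: Optional[StateVector] = None,
    dt: float = 0.005,
    rhs_override: Optional[Callable[[float, np.ndarray], np.ndarray]] = None,
    y0_override: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Classical fixed-step 4th-order Runge-Kutta integration of the same RHS.

    A deliberately simple cross-check for ``safe_solve``; with
    ``rhs_override``/``y0_override`` it integrates an arbitrary system
    (used to validate the stepper against closed-form solutions).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")

    grid = np.linspace(0.0, config.duration, config.n_points)
    if rhs_override is not None:
        rhs = rhs_override
        y = np.asarray(y0_override, dtype=float)
        n_extra = 0
        schedules = []
        current_doses: Dict[int, float] = {}
        bounds = [0.0, float(config.duration)]
    else:
        y0_core = as_state_array(initial if initial is not None else initial_state())
        y0_core[7] = max(y0_core[7], params.resistance_floor)
        y0_core[8] = max(y0_core[8], params.resistance_floor)
        schedules = protocol.schedules
        n_extra = len(schedules)
        current_doses = {i: s.dose for i, s in enumerate(schedules) if s.kind == "adaptive"}
        rhs = build_rhs(config, params, protocol, current_doses)
        y = np.concatenate([y0_core, np.zeros(n_extra)])
        bounds = _segments(config, protocol)

    sample_t = [0.0]
    sample_y = [y.copy()]
    t = max(bounds[0], config.t_start if rhs_override is None else 0.0)
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        t = max(t0, t)
        n_steps = max(1, int(round((t1 - t) / dt)))
        h = (t1 - t) / n_steps
        next_grid = grid[(grid > t0 + 1e-12) & (grid <= t1 + 1e-12)]
        gi = 0
        for _ in range(n_steps):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            while gi < len(next_grid) and t >= next_grid[gi] - 1e-9:
                sample_t.append(float(next_grid[gi]))
                sample_y.append(y.copy())
                gi += 1
        if current_doses and t1 < config.duration:
            times_arr = np.array(sample_t)
            burdens = np.array([_burden(np.maximum(s[:15], config.floor)) for s in sample_y])
            for i, sched in enumerate(schedules):
                if sched.kind != "adaptive":
                    continue
                prev = float(np.interp(t1 - sched.monitoring_period, times_arr, burdens))
                current_doses[i] = update_adaptive_dose(
                    current_doses[i], burdens[-1] / prev, sched
                )

    full = np.vstack(sample_y)
    if rhs_override is not None:
        return SimulationResult(
            times=np.array(sample_t), states=full, drug_concentrations={},
            doses={}, temperature=np.full(len(sample_t), 37.0),
            method_used="RK4-fixed", fallback_level=0, converged=True, is_dummy=False,
        )
    states = np.maximum(full[:, :15], config.floor)
    conc: Dict[str, np.ndarray] = {}
    for i, sched in enumerate(schedules):
        c = np.maximum(full[:, 15 + i], 0.0)
        conc[sched.drug_type] = conc.get(sched.drug_type, 0.0) + c
    return SimulationResult(
        times=np.array(sample_t), states=states, drug_concentrations=conc,
        doses={}, temperature=np.full(len(sample_t), 37.0),
        method_used="RK4-fixed", fallback_level=0, converged=True, is_dummy=False,
    )
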