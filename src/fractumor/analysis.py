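"""Outcome metrics, the comparative experiment grid and sensitivity analysis.

Outcomes of a simulated treatment course are summarised by three
metrics computed on the daily trajectory:

* ``percent_reduction`` = 100 * (1 - final_burden / initial_burden)
* ``resistance_fraction`` = 100 * (R1 + R2) / total burden at the final day
* ``efficacy_score`` = percent_reduction / (1 + resistance_fraction / 100)

The comparative grid runs one simulation per (alpha, profile, protocol)
combination; the default design is 7 alpha values x 4 profiles x
5 protocols = 140 runs.  The local sensitivity engine perturbs each of
the 58 parameters by +-10% and +-20% in each of the 20 profile x
protocol contexts (4,640 runs) and reports normalized sensitivity
coefficients S = (dO/O) / (dp/p), with per-parameter maxima |S|_max
classified as critical (>= 1.0), important (>= 0.5) or non-critical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort import (
    PROFILE_NAMES,
    PROTOCOL_NAMES,
    apply_profile,
    make_patient_profile,
    make_protocol,
)
from .parameters import (
    PARAMETER_CATEGORIES,
    PARAMETER_GROUPS,
    PARAMETER_NAMES,
    ModelParameters,
    ParameterError,
    baseline_parameters,
)
from .solver import SimulationConfig, SimulationResult, safe_solve

#: fractional-order sweep used throughout the comparative experiments
DEFAULT_ALPHAS = (0.75, 0.80, 0.85, 0.90, 0.93, 0.95, 1.00)

METRICS = ("percent_reduction", "resistance_fraction", "efficacy_score")


class UndefinedMetricError(ValueError):
    """Raised when an outcome metric cannot be computed."""


@dataclass
class OutcomeMetrics:
    initial_burden: float
    final_burden: float
    percent_reduction: float
    resistance_fraction: float
    efficacy_score: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "initial_burden": self.initial_burden,
            "final_burden": self.final_burden,
            "percent_reduction": self.percent_reduction,
            "resistance_fraction": self.resistance_fraction,
            "efficacy_score": self.efficacy_score,
        }


def outcome_metrics(result: SimulationResult) -> OutcomeMetrics:
    """Treatment outcome metrics from the first and last daily samples."""
    if not result.converged:
        raise UndefinedMetricError("metrics undefined for a non-converged result")
    first, last = result.states[0], result.states[-1]
    burden = lambda y: float(y[0] + y[1] + y[6] + y[7] + y[8] + y[9])
    initial, final = burden(first), burden(last)
    if initial <= 0:
        raise UndefinedMetricError("initial tumor burden is zero")
    reduction = 100.0 * (1.0 - final / initial)
    resistance = 100.0 * float(last[7] + last[8]) / final
    efficacy = reduction / (1.0 + resistance / 100.0)
    return OutcomeMetrics(initial, final, reduction, resistance, efficacy)


def grid_design(
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    profiles: Sequence[str] = PROFILE_NAMES,
    protocols: Sequence[str] = PROTOCOL_NAMES,
) -> List[Tuple[float, str, str]]:
    """Deterministic (alpha, profile, protocol) key order for the grid."""
    return [
        (float(a), pf, pr)
        for a in sorted(alphas)
        for pf in sorted(profiles)
        for pr in sorted(protocols)
    ]


def _run_cell(
    alpha: float,
    profile_name: str,
    protocol_name: str,
    baseline: ModelParameters,
    config: SimulationConfig,
) -> Dict[str, object]:
    profile = make_patient_profile(profile_name)
    params = apply_profile(baseline, profile)
    protocol = make_protocol(protocol_name, profile)
    cfg = replace(config, alpha=alpha)
    result = safe_solve(cfg, params, protocol)
    row: Dict[str, object] = {
        "alpha": alpha,
        "profile": profile_name,
        "protocol": protocol_name,
        "converged": result.converged,
        "method": result.method_used,
        "fallback_level": result.fallback_level,
    }
    if result.converged:
        row.update(outcome_metrics(result).as_dict())
    else:
        row.update({k: np.nan for k in (
            "initial_burden", "final_burden", "percent_reduction",
            "resistance_fraction", "efficacy_score")})
    return row


def run_grid(
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    profiles: Sequence[str] = PROFILE_NAMES,
    protocols: Sequence[str] = PROTOCOL_NAMES,
    config: Optional[SimulationConfig] = None,
    params: Optional[ModelParameters] = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """One simulation per (alpha, profile, protocol); deterministic row order."""
    config = config or SimulationConfig()
    baseline = params or baseline_parameters()
    keys = grid_design(alphas, profiles, protocols)
    if n_jobs == 1:
        rows = [_run_cell(a, pf, pr, baseline, config) for a, pf, pr in keys]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_run_cell)(a, pf, pr, baseline, config) for a, pf, pr in keys
        )
    return pd.DataFrame(rows)


def _slice(grid: pd.DataFrame, alpha: Optional[float], profile: Optional[str]) -> pd.DataFrame:
    out = grid[grid["converged"]]
    if alpha is not None:
        out = out[np.isclose(out["alpha"], alpha)]
    if profile is not None and profile != "average-over-profiles":
        out = out[out["profile"] == profile]
    if out.empty:
        raise KeyError(f"grid has no rows for alpha={alpha}, profile={profile}")
    if profile == "average-over-profiles":
        out = (
            out.groupby("protocol", as_index=False)[list(METRICS)].mean()
            .assign(alpha=alpha, profile=profile, converged=True)
        )
    return out


def rank_protocols(grid: pd.DataFrame, alpha: float, profile: str = "average") -> pd.DataFrame:
    """Protocols in descending efficacy order for one (alpha, profile) slice.

    Ties break on higher percent reduction, then alphabetical protocol name.
    """
    sl = _slice(grid, alpha, profile).copy()
    sl = sl.sort_values(
        by=["efficacy_score", "percent_reduction", "protocol"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    sl.index = sl.index + 1
    sl.index.name = "rank"
    return sl[["protocol", "efficacy_score", "percent_reduction", "resistance_fraction"]]


def optimal_protocol(grid: pd.DataFrame, profile: str, alpha: float) -> Tuple[str, float]:
    """argmax of efficacy over protocols for one (profile, alpha) slice."""
    ranking = rank_protocols(grid, alpha, profile)
    if ranking.empty:
        raise UndefinedMetricError("no converged rows in the requested slice")
    top = ranking.iloc[0]
    return str(top["protocol"]), float(top["efficacy_score"])


def protocol_variability(grid: pd.DataFrame, profile: str = "average") -> pd.DataFrame:
    """Per-protocol min/max/range/sd/CV of efficacy across the alpha sweep.

    Sample standard deviation (ddof=1); CV = 100 * sd / mean.
    """
    sl = grid[(grid["profile"] == profile) & grid["converged"]]
    rows = []
    for protocol, grp in sl.groupby("protocol"):
        if grp["alpha"].nunique() < 2:
            raise UndefinedMetricError("variability needs at least two alpha values")
        eff = grp["efficacy_score"].to_numpy()
        sd = float(np.std(eff, ddof=1))
        rows.append({
            "protocol": protocol,
            "min_efficacy": float(eff.min()),
            "max_efficacy": float(eff.max()),
            "range": float(eff.max() - eff.min()),
            "std": sd,
            "cv_percent": 100.0 * sd / float(eff.mean()),
        })
    return pd.DataFrame(rows).sort_values("range", ascending=False).reset_index(drop=True)


def compare_fractional_integer(grid: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Compare pooled fractional-order (alpha < 1) rows against alpha = 1 rows.

    Returns aggregate means +- sd of the three metrics, per-context percent
    differences of efficacy (pooled and best-alpha conventions), and
    per-profile / per-protocol means.  Percent difference is
    100 * (fractional - integer) / integer.
    """
    ok = grid[grid["converged"]]
    integer = ok[np.isclose(ok["alpha"], 1.0)]
    fractional = ok[ok["alpha"] < 1.0]
    if integer.empty:
        raise UndefinedMetricError("grid has no alpha = 1.0 rows")
    if fractional.empty:
        raise UndefinedMetricError("grid has no alpha < 1.0 rows")

    agg_rows = []
    for metric in METRICS:
        i, f = integer[metric], fractional[metric]
        agg_rows.append({
            "metric": metric,
            "integer_mean": i.mean(), "integer_sd": i.std(ddof=1),
            "fractional_mean": f.mean(), "fractional_sd": f.std(ddof=1),
            "difference": f.mean() - i.mean(),
            "difference_percent": 100.0 * (f.mean() - i.mean()) / i.mean(),
        })
    aggregate = pd.DataFrame(agg_rows)

    ctx_rows = []
    for (pf, pr), grp in ok.groupby(["profile", "protocol"]):
        i_rows = grp[np.isclose(grp["alpha"], 1.0)]
        f_rows = grp[grp["alpha"] < 1.0]
        if i_rows.empty or f_rows.empty:
            continue
        ieff = float(i_rows["efficacy_score"].iloc[0])
        pooled = float(f_rows["efficacy_score"].mean())
        best_idx = f_rows["efficacy_score"].idxmax()
        ctx_rows.append({
            "profile": pf, "protocol": pr,
            "integer_efficacy": ieff,
            "fractional_efficacy": pooled,
            "difference_percent": 100.0 * (pooled - ieff) / ieff,
            "best_alpha": float(f_rows.loc[best_idx, "alpha"]),
            "best_fractional_efficacy": float(f_rows.loc[best_idx, "efficacy_score"]),
            "best_difference_percent":
                100.0 * (float(f_rows.loc[best_idx, "efficacy_score"]) - ieff) / ieff,
        })
    per_context = pd.DataFrame(ctx_rows)

    def _by(level: str) -> pd.DataFrame:
        rows = []
        for key, grp in ok.groupby(level):
            i = grp[np.isclose(grp["alpha"], 1.0)]["efficacy_score"].mean()
            f = grp[grp["alpha"] < 1.0]["efficacy_score"].mean()
            rows.append({
                level: key, "integer_efficacy": i, "fractional_efficacy": f,
                "difference_percent": 100.0 * (f - i) / i,
            })
        return pd.DataFrame(rows)

    return {
        "aggregate": aggregate,
        "per_context": per_context,
        "per_profile": _by("profile"),
        "per_protocol": _by("protocol"),
    }


# ---------------------------------------------------------------------------
# local sensitivity analysis
# ---------------------------------------------------------------------------

DEFAULT_LEVELS = (-0.20, -0.10, 0.10, 0.20)


def sensitivity_design(
    parameter_names: Sequence[str] = PARAMETER_NAMES,
    profiles: Sequence[str] = PROFILE_NAMES,
    protocols: Sequence[str] = PROTOCOL_NAMES,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> List[Tuple[str, str, str, float]]:
    """All (parameter, profile, protocol, level) perturbation runs."""
    return [
        (p, pf, pr, lv)
        for p in parameter_names
        for pf in sorted(profiles)
        for pr in sorted(protocols)
        for lv in levels
    ]


def _default_simulate(
    params: ModelParameters, protocol_name: str, config: SimulationConfig
) -> Optional[Dict[str, float]]:
    result = safe_solve(config, params, make_protocol(protocol_name))
    if not result.converged:
        return None
    m = outcome_metrics(result)
    return {k: getattr(m, k) for k in METRICS}


def classify_sensitivity(s_max: float) -> str:
    """Critical / important / non-critical bands; boundaries classify upward."""
    if abs(s_max) >= 1.0:
        return "critical"
    if abs(s_max) >= 0.5:
        return "important"
    return "non-critical"


@dataclass
class SensitivityResult:
    records: pd.DataFrame        # one row per parameter x context x level x metric
    ranking: pd.DataFrame        # per-parameter |S|_max on the ranking metric
    by_category: pd.DataFrame    # mean |S|_max per functional group
    by_source: pd.DataFrame      # mean |S|_max per evidence category
    attempted: int
    retained: int

    @property
    def retention(self) -> float:
        return self.retained / self.attempted if self.attempted else 0.0


def sensitivity_analysis(
    baseline: Optional[ModelParameters] = None,
    parameter_names: Sequence[str] = PARAMETER_NAMES,
    profiles: Sequence[str] = PROFILE_NAMES,
    protocols: Sequence[str] = PROTOCOL_NAMES,
    levels: Sequence[float] = DEFAULT_LEVELS,
    config: Optional[SimulationConfig] = None,
    ranking_metric: str = "efficacy_score",
    simulate_fn: Optional[Callable[..., Optional[Dict[str, float]]]] = None,
    n_jobs: int = 1,
) -> SensitivityResult:
    """One-at-a-time local sensitivity analysis.

    Each parameter is perturbed multiplicatively at each ``level`` within
    each profile x protocol context (the perturbation applies to the
    context's effective parameter value, after profile modifications).
    The fractional order itself is a study dimension, not a parameter, and
    is never perturbed; the analysis runs at ``config.alpha`` (default
    integer order).  ``simulate_fn(params, protocol_name, config)`` may be
    injected to replace the simulator (returns a metric dict or None for a
    non-converged run); this is how the engine is validated against
    closed-form responses.
    """
    baseline = baseline or baseline_parameters()
    config = config or SimulationConfig()
    simulate = simulate_fn or _default_simulate

    contexts = [(pf, pr) for pf in sorted(profiles) for pr in sorted(protocols)]

    base_outcomes: Dict[Tuple[str, str], Optional[Dict[str, float]]] = {}
    ctx_params: Dict[Tuple[str, str], ModelParameters] = {}
    for pf, pr in contexts:
        params = apply_profile(baseline, make_patient_profile(pf))
        ctx_params[(pf, pr)] = params
        base_outcomes[(pf, pr)] = simulate(params, pr, config)

    def _one(param: str, pf: str, pr: str, level: float) -> List[Dict[str, object]]:
        base = base_outcomes[(pf, pr)]
        params = ctx_params[(pf, pr)]
        value = getattr(params, param)
        try:
            perturbed = params.replace(**{param: value * (1.0 + level)})
        except ParameterError:
            # perturbation leaves the parameter's domain (e.g. bioavailability
            # pushed above 1): excluded and counted like a non-converged run
            perturbed = None
        out = simulate(perturbed, pr, config) if perturbed is not None else None
        rows = []
        for metric in METRICS:
            rec: Dict[str, object] = {
                "parameter": param,
                "category": PARAMETER_GROUPS[param],
                "source": PARAMETER_CATEGORIES[param],
                "profile": pf,
                "protocol": pr,
                "level": level,
                "metric": metric,
            }
            if base is None or out is None:
                rec.update({"S": np.nan, "converged": False})
            elif base[metric] == 0:
                rec.update({"S": np.nan, "converged": False})
            else:
                rec.update({
                    "S": ((out[metric] - base[metric]) / base[metric]) / level,
                    "converged": True,
                })
            rows.append(rec)
        return rows

    design = sensitivity_design(parameter_names, profiles, protocols, levels)
    if n_jobs == 1:
        nested = [_one(*run) for run in design]
    else:
        nested = Parallel(n_jobs=n_jobs)(delayed(_one)(*run) for run in design)
    records = pd.DataFrame([r for rows in nested for r in rows])

    ok = records[(records["metric"] == ranking_metric) & records["converged"]]
    rank_rows = []
    for param, grp in ok.groupby("parameter"):
        s_max = float(grp["S"].abs().max())
        rank_rows.append({
            "parameter": param,
            "category": PARAMETER_GROUPS[param],
            "source": PARAMETER_CATEGORIES[param],
            "s_max": s_max,
            "classification": classify_sensitivity(s_max),
        })
    ranking = (
        pd.DataFrame(rank_rows)
        .sort_values(["s_max", "parameter"], ascending=[False, True])
        .reset_index(drop=True)
    )
    ranking.index = ranking.index + 1
    ranking.index.name = "rank"

    by_category = ranking.groupby("category", as_index=False)["s_max"].mean()
    by_source = ranking.groupby("source", as_index=False)["s_max"].mean()

    per_run = records[records["metric"] == ranking_metric]
    retained = int(per_run["converged"].sum())
    return SensitivityResult(
        records=records,
        ranking=ranking,
        by_category=by_category.sort_values("s_max", ascending=False).reset_index(drop=True),
        by_source=by_source.sort_values("s_max", ascending=False).reset_index(drop=True),
        attempted=len(design),
        retained=retained,
    )
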