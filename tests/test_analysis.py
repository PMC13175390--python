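"""Outcome metrics, grid machinery, rankings, comparisons, sensitivity engine."""

import numpy as np
import pandas as pd
import pytest

from fractumor import (
    SimulationConfig,
    compare_fractional_integer,
    grid_design,
    make_protocol,
    optimal_protocol,
    outcome_metrics,
    protocol_variability,
    rank_protocols,
    run_grid,
    safe_solve,
    sensitivity_analysis,
    sensitivity_design,
)
from fractumor.analysis import METRICS, UndefinedMetricError, classify_sensitivity
from fractumor.solver import SimulationResult


def _fake_result(initial_burden, final_n1, final_r1, final_r2):
    states = np.full((3, 15), 1e-6)
    states[0, 0] = initial_burden
    states[:, 2] = 10.0
    states[2, 0], states[2, 7], states[2, 8] = final_n1, final_r1, final_r2
    return SimulationResult(
        times=np.array([0.0, 1.0, 2.0]), states=states, drug_concentrations={},
        doses={}, temperature=np.full(3, 37.0), method_used="RK45",
        fallback_level=0, converged=True, is_dummy=False,
    )


def _grid_row(alpha, profile, protocol, eff, red=None, rf=1.0):
    red = eff * (1 + rf / 100) if red is None else red
    return {
        "alpha": alpha, "profile": profile, "protocol": protocol,
        "efficacy_score": eff, "percent_reduction": red,
        "resistance_fraction": rf, "converged": True,
        "initial_burden": 202.2, "final_burden": 202.2 * (1 - red / 100),
        "method": "RK45", "fallback_level": 0,
    }


class TestOutcomeMetrics:
    def test_no_change_is_zero_efficacy(self):
        m = outcome_metrics(_fake_result(100.0, 100.0 - 2e-6, 1e-6, 1e-6))
        assert m.percent_reduction == pytest.approx(0.0, abs=1e-5)
        assert m.efficacy_score == pytest.approx(0.0, abs=1e-5)

    def test_zero_resistance_efficacy_equals_reduction(self):
        m = outcome_metrics(_fake_result(100.0, 70.0, 1e-6, 1e-6))
        assert m.percent_reduction == pytest.approx(30.0, abs=1e-4)
        assert m.efficacy_score == pytest.approx(m.percent_reduction)

    def test_resistance_discounts_efficacy(self):
        # reduction 32.76%, resistance 1.55% -> efficacy 32.26
        final = 202.2 * (1 - 0.3276)
        rf = 0.0155 * final
        m = outcome_metrics(_fake_result(202.2, final - rf, rf / 2, rf / 2))
        assert m.percent_reduction == pytest.approx(32.76, abs=0.01)
        assert m.resistance_fraction == pytest.approx(1.55, abs=0.01)
        assert m.efficacy_score == pytest.approx(32.26, abs=0.01)

    def test_efficacy_never_exceeds_reduction(self, baseline):
        cfg = SimulationConfig(duration=30.0, n_points=31)
        m = outcome_metrics(safe_solve(cfg, baseline, make_protocol("standard")))
        assert m.efficacy_score <= m.percent_reduction


class TestGrid:
    def test_default_design_is_140_runs(self):
        assert len(grid_design()) == 140

    def test_grid_of_one_matches_direct_call(self, baseline):
        cfg = SimulationConfig(duration=20.0, n_points=21, alpha=0.9)
        grid = run_grid(alphas=[0.9], profiles=["average"], protocols=["standard"],
                        config=cfg)
        direct = outcome_metrics(safe_solve(cfg, baseline, make_protocol("standard")))
        assert len(grid) == 1
        assert grid.loc[0, "efficacy_score"] == pytest.approx(direct.efficacy_score)

    def test_worker_count_does_not_change_results(self):
        cfg = SimulationConfig(duration=15.0, n_points=16)
        kwargs = dict(alphas=[0.8, 1.0], profiles=["average"],
                      protocols=["standard", "continuous"], config=cfg)
        serial = run_grid(n_jobs=1, **kwargs)
        parallel = run_grid(n_jobs=2, **kwargs)
        pd.testing.assert_frame_equal(serial, parallel)


class TestRanking:
    def _grid(self):
        rows = [
            _grid_row(0.75, "average", "continuous", 32.26, red=32.76),
            _grid_row(0.75, "average", "adaptive", 30.88),
            _grid_row(0.75, "average", "standard", 30.65),
            _grid_row(0.75, "average", "immuno_combo", 25.71),
        ]
        return pd.DataFrame(rows)

    def test_descending_order(self):
        ranking = rank_protocols(self._grid(), 0.75, "average")
        assert list(ranking["protocol"]) == [
            "continuous", "adaptive", "standard", "immuno_combo"]

    def test_tie_breaks_alphabetical(self):
        rows = [
            _grid_row(0.8, "average", "standard", 30.0, red=31.0),
            _grid_row(0.8, "average", "adaptive", 30.0, red=31.0),
        ]
        ranking = rank_protocols(pd.DataFrame(rows), 0.8, "average")
        assert list(ranking["protocol"]) == ["adaptive", "standard"]

    def test_optimal_is_argmax_and_stable_under_worse_entry(self):
        grid = self._grid()
        name, eff = optimal_protocol(grid, "average", 0.75)
        assert (name, eff) == ("continuous", 32.26)
        worse = pd.concat(
            [grid, pd.DataFrame([_grid_row(0.75, "average", "hyperthermia", 1.0)])],
            ignore_index=True)
        assert optimal_protocol(worse, "average", 0.75)[0] == "continuous"

    def test_missing_slice_rejected(self):
        with pytest.raises(KeyError):
            rank_protocols(self._grid(), 0.95, "average")


class TestVariability:
    def test_range_and_cv(self):
        effs = [30.09, 30.11, 30.45, 30.74, 31.65, 31.48, 32.26]
        rows = [_grid_row(a, "average", "continuous", e)
                for a, e in zip((0.75, 0.8, 0.85, 0.9, 0.93, 0.95, 1.0), effs)]
        out = protocol_variability(pd.DataFrame(rows), "average")
        row = out.iloc[0]
        assert row["range"] == pytest.approx(32.26 - 30.09)
        sd = np.std(effs, ddof=1)
        assert row["std"] == pytest.approx(sd)
        assert row["cv_percent"] == pytest.approx(100 * sd / np.mean(effs))

    def test_constant_efficacy_zero_spread(self):
        rows = [_grid_row(a, "average", "standard", 30.0) for a in (0.8, 0.9, 1.0)]
        out = protocol_variability(pd.DataFrame(rows), "average")
        assert out.iloc[0]["range"] == 0.0 and out.iloc[0]["cv_percent"] == 0.0


class TestCompareFractionalInteger:
    def test_identical_alphas_zero_difference(self):
        rows = [_grid_row(a, "average", "standard", 30.0) for a in (0.75, 0.9, 1.0)]
        tables = compare_fractional_integer(pd.DataFrame(rows))
        assert tables["aggregate"]["difference_percent"].abs().max() == pytest.approx(0.0)
        assert tables["per_context"]["difference_percent"].iloc[0] == pytest.approx(0.0)

    def test_two_row_difference(self):
        rows = [
            _grid_row(1.0, "young", "continuous", 30.19),
            _grid_row(0.8, "young", "continuous", 31.30),
        ]
        tables = compare_fractional_integer(pd.DataFrame(rows))
        ctx = tables["per_context"].iloc[0]
        assert ctx["difference_percent"] == pytest.approx(100 * (31.30 - 30.19) / 30.19)
        assert ctx["best_alpha"] == 0.8

    def test_best_alpha_convention(self):
        rows = [
            _grid_row(1.0, "young", "continuous", 30.19),
            _grid_row(0.8, "young", "continuous", 32.38),
            _grid_row(0.75, "young", "continuous", 31.00),
        ]
        ctx = compare_fractional_integer(pd.DataFrame(rows))["per_context"].iloc[0]
        assert ctx["best_fractional_efficacy"] == 32.38
        assert ctx["best_difference_percent"] == pytest.approx(
            100 * (32.38 - 30.19) / 30.19)

    def test_missing_integer_rows_rejected(self):
        rows = [_grid_row(0.8, "average", "standard", 30.0)]
        with pytest.raises(UndefinedMetricError):
            compare_fractional_integer(pd.DataFrame(rows))


class TestSensitivity:
    def test_full_design_is_4640_runs(self):
        assert len(sensitivity_design()) == 4640

    def test_classification_bands(self):
        assert classify_sensitivity(1.2) == "critical"
        assert classify_sensitivity(1.0) == "critical"   # boundary upward
        assert classify_sensitivity(0.7) == "important"
        assert classify_sensitivity(0.5) == "important"
        assert classify_sensitivity(0.49) == "non-critical"

    def test_linear_response_recovers_unit_sensitivity(self):
        """O = c * p gives S = 1 exactly at every level and context."""
        def simulate(params, protocol_name, config):
            return {m: 3.0 * params.beta1 for m in METRICS}

        res = sensitivity_analysis(
            parameter_names=["beta1"], simulate_fn=simulate,
            profiles=["average"], protocols=["standard", "continuous"])
        assert np.allclose(res.records["S"], 1.0, atol=1e-12)
        assert res.ranking.loc[1, "s_max"] == pytest.approx(1.0, abs=1e-12)

    def test_affine_response_matches_closed_form(self):
        """O = a + b*p gives S = b*p/(a + b*p) at the baseline."""
        a, b = 10.0, 40.0

        def simulate(params, protocol_name, config):
            return {m: a + b * params.kappa_q for m in METRICS}

        res = sensitivity_analysis(
            parameter_names=["kappa_q"], simulate_fn=simulate,
            profiles=["average"], protocols=["standard"])
        p = 0.001  # baseline kappa_q
        expected = b * p / (a + b * p)
        assert np.allclose(res.records["S"], expected, atol=1e-10)

    def test_out_of_domain_perturbation_excluded_not_fatal(self):
        """Bioavailability 0.85 * 1.2 > 1 must be excluded, not crash."""
        def simulate(params, protocol_name, config):
            return {m: 30.0 * params.bioavailability for m in METRICS}

        res = sensitivity_analysis(
            parameter_names=["bioavailability"], simulate_fn=simulate,
            profiles=["average"], protocols=["standard"])
        bad = res.records[res.records["level"] == 0.2]
        good = res.records[res.records["level"] != 0.2]
        assert not bad["converged"].any()
        assert good["converged"].all()
        assert np.allclose(good["S"], 1.0, atol=1e-12)
        assert res.retained == 3 and res.attempted == 4

    def test_nonconverged_runs_counted_not_imputed(self):
        calls = {"n": 0}

        def simulate(params, protocol_name, config):
            calls["n"] += 1
            return None if protocol_name == "standard" else {m: 1.0 for m in METRICS}

        res = sensitivity_analysis(
            parameter_names=["beta1"], simulate_fn=simulate,
            profiles=["average"], protocols=["standard", "continuous"])
        assert res.attempted == 8
        assert res.retained == 4
        bad = res.records[res.records["protocol"] == "standard"]
        assert not bad["converged"].any()
        assert bad["S"].isna().all()
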