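"""Core dynamics: burden, intermediates, circadian/memory factors, the RHS."""

import math

import mpmath
import numpy as np
import pytest

from fractumor import (
    ControlInputs,
    StateVector,
    baseline_parameters,
    circadian_factor,
    compute_intermediates,
    derivatives,
    fractional_factor,
    initial_state,
    total_tumor_burden,
)
from fractumor.fixtures import random_parameters
from fractumor.parameters import ParameterError
from fractumor.state import InvalidStateError

from _rhs_oracle import oracle_rhs


class TestTotalTumorBurden:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (StateVector(N1=190, N2=10, Q=0.1, R1=1, R2=1, S=0.1), 202.2),
            (StateVector(), 0.0),
            # immune cells, drugs and microenvironment must not count
            (StateVector(I1=40, I2=10, P=5, A=3, D=2, Dm=1, G=1, M=1, H=1), 0.0),
        ],
    )
    def test_values(self, state, expected):
        assert total_tumor_burden(state) == pytest.approx(expected)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(InvalidStateError):
            total_tumor_burden(StateVector(N1=float("nan")))


class TestIntermediates:
    def test_reference_initial_state(self, baseline):
        inter = compute_intermediates(0.0, initial_state(), baseline, ControlInputs())
        assert inter.total_tumor == pytest.approx(202.2)
        # 0.2022 below the 0.3 hypoxia threshold: normoxic, full immune efficacy
        assert inter.hypoxia_factor == 0.0
        assert inter.immune_kill_factor == 1.0
        assert inter.carrying_capacity_factor == pytest.approx(1 - 202.2 / 1000)

    def test_carrying_capacity_boundary(self, baseline):
        state = StateVector(N1=baseline.carrying_capacity)
        inter = compute_intermediates(0.0, state, baseline, ControlInputs())
        assert inter.carrying_capacity_factor == pytest.approx(0.0, abs=1e-8)
        assert inter.hypoxia_factor == pytest.approx(1.0, rel=1e-6)

    def test_therapy_effect_linear_combination(self, baseline):
        controls = ControlInputs(uE=1.0, uH=1.0, uC=1.0)
        inter = compute_intermediates(0.0, initial_state(), baseline, controls)
        assert inter.therapy_effect == pytest.approx(0.03)

    def test_invariants_on_random_states(self, baseline, rng):
        for _ in range(200):
            state = StateVector.from_array(rng.uniform(1e-6, 400.0, 15))
            inter = compute_intermediates(0.0, state, baseline, ControlInputs())
            assert 0.0 <= inter.carrying_capacity_factor <= 1.0
            assert 0.0 <= inter.hypoxia_factor <= 1.0 or inter.total_tumor > baseline.carrying_capacity
            assert 0.0 < inter.immune_kill_factor <= 1.0
            assert inter.acidosis_effect >= 1.0
            assert inter.quiescence_factor >= 1.0

    def test_bad_carrying_capacity_rejected(self, baseline):
        with pytest.raises(ParameterError):
            baseline.replace(carrying_capacity=-1.0)


class TestCircadianFactor:
    def test_phase_zero_at_t_zero(self, baseline):
        assert circadian_factor(0.0, baseline) == pytest.approx(1.0)

    def test_quarter_period_peak(self, baseline):
        # 6 h into a 24 h cycle, amplitude 0.2 -> 1.2
        assert circadian_factor(0.25, baseline) == pytest.approx(1.2)

    def test_disabled_is_identity(self, baseline):
        params = baseline.replace(circadian_enabled=False)
        for t in (0.0, 0.3, 17.2):
            assert circadian_factor(t, params) == 1.0

    def test_bounded_by_amplitude(self, baseline, rng):
        for t in rng.uniform(0, 100, 50):
            f = circadian_factor(float(t), baseline)
            assert 1 - baseline.circadian_amplitude <= f <= 1 + baseline.circadian_amplitude

    def test_excessive_amplitude_rejected(self, baseline):
        with pytest.raises(ParameterError):
            baseline.replace(circadian_amplitude=1.0)


class TestFractionalFactor:
    @pytest.mark.parametrize(
        "t, alpha, expected",
        [
            (0.0, 0.8, 1.0),              # pre-treatment branch
            (-1.0, 0.9, 1.0),
            (5.0, 1.0, 0.01),             # memoryless case: bare scaling
            (1.0, 0.75, 0.0125),          # t^-alpha = 1 at t = 1
            (2.0, 0.75, float(0.01 * (1 + 0.25 * mpmath.mpf(2) ** mpmath.mpf("-0.75")))),
        ],
    )
    def test_values(self, t, alpha, expected):
        assert fractional_factor(t, alpha) == pytest.approx(expected, rel=1e-12)

    def test_invalid_alpha_rejected(self):
        for alpha in (0.0, -0.5, 1.5):
            with pytest.raises(ParameterError):
                fractional_factor(1.0, alpha)

    def test_monotone_in_time_and_alpha(self):
        ts = np.linspace(0.5, 400, 200)
        vals = [fractional_factor(t, 0.8) for t in ts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        for t in (1.0, 10.0, 250.0):
            by_alpha = [fractional_factor(t, a) for a in (0.75, 0.85, 0.95, 1.0)]
            assert all(a >= b for a, b in zip(by_alpha, by_alpha[1:]))


class TestDerivatives:
    def test_immune_baseline_without_tumor(self, baseline):
        """With no tumor and no drugs, dI1/dt is production minus death."""
        state = StateVector(I1=25.0, I2=1e-6, G=1.0)
        d = derivatives(3.0, state, baseline, ControlInputs(), alpha=0.9)
        gamma = fractional_factor(3.0, 0.9)
        delta_i = baseline.delta_i * circadian_factor(3.0, baseline)
        # the 1e-6 nonnegativity floor leaves a ~6e-6 residual tumor burden,
        # so the tumor-coupled immune terms contribute only at ~1e-10 scale
        assert d[2] == pytest.approx((baseline.phi1 - delta_i * 25.0) * gamma, abs=1e-9)

    def test_drug_mass_transfer(self, baseline):
        state = StateVector(D=1.0, G=1.0)
        d = derivatives(2.0, state, baseline, ControlInputs(), alpha=1.0)
        gamma = fractional_factor(2.0, 1.0)
        assert d[10] == pytest.approx(-0.1 * gamma)
        assert d[11] == pytest.approx(+0.1 * gamma)
        assert d[10] + d[11] == pytest.approx(0.0, abs=1e-18)

    def test_oracle_equivalence_initial_state(self, baseline, y0):
        got = derivatives(0.0, y0, baseline, ControlInputs(), alpha=1.0)
        want = oracle_rhs(0.0, y0, baseline)
        np.testing.assert_allclose(got, want, rtol=1e-13)

    def test_oracle_equivalence_random(self, rng):
        """Modular RHS equals the monolithic transcription on 1,000 draws."""
        for _ in range(1000):
            params = random_parameters(rng)
            y = rng.uniform(1e-6, 500.0, 15)
            y[12] = rng.uniform(0.0, 1.0)
            t = float(rng.uniform(0.0, 500.0))
            alpha = float(rng.uniform(0.75, 1.0))
            u = rng.uniform(0, 1, 4)
            ib = 1.0 + params.immuno_resist_boost * u[3]
            controls = ControlInputs(uE=u[0], uH=u[1], uC=u[2], uI=u[3],
                                     temperature=float(rng.uniform(37, 39.5)),
                                     immuno_boost=ib)
            rm = float(rng.uniform(0.5, 2.5))
            din = float(rng.uniform(0, 0.01))
            got = derivatives(t, y, params, controls, alpha=alpha,
                              resistance_multiplier=rm, drug_input=din)
            want = oracle_rhs(t, y, params, uE=u[0], uH=u[1], uC=u[2], uI=u[3],
                              temperature=controls.temperature, immuno_boost=ib,
                              alpha=alpha, resistance_multiplier=rm, drug_input=din)
            scale = np.maximum(np.abs(want), 1e-30)
            assert np.max(np.abs(got - want) / scale) < 1e-12

    def test_growth_nonincreasing_in_total_burden(self, baseline):
        """Logistic crowding: growth flux falls as total burden rises."""
        def growth_n1(extra_q):
            state = StateVector(N1=100.0, Q=extra_q, I1=1e-6, G=1.0, M=1.0)
            inter = compute_intermediates(0.0, state, baseline, ControlInputs())
            return baseline.lambda1 * 100.0 * inter.growth_factor / inter.acidosis_effect

        fluxes = [growth_n1(q) for q in (0.0, 100.0, 400.0, 800.0)]
        assert all(a > b for a, b in zip(fluxes, fluxes[1:]))

    def test_time_invariant_without_circadian(self, baseline, y0):
        """With circadian off, the RHS depends on t only via the memory factor."""
        params = baseline.replace(circadian_enabled=False)
        d1 = derivatives(3.3, y0, params, ControlInputs(), alpha=0.8)
        d2 = derivatives(47.9, y0, params, ControlInputs(), alpha=0.8)
        np.testing.assert_allclose(
            d1 / fractional_factor(3.3, 0.8),
            d2 / fractional_factor(47.9, 0.8),
            rtol=1e-12,
        )
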