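"""QSSA RhoA dynamics, Cdc42 branch, biosensor layer, and the mass-action oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optorho import (
    FullModelParams,
    KineticParams,
    PulseProtocol,
    RecruitmentParams,
    Trace,
    pulse_jump_factor,
    qssa_full_discrepancy,
    simulate_biosensor,
    simulate_cdc42,
    simulate_cell,
    simulate_full,
    simulate_recruitment,
    simulate_rhoa,
    step_input,
)
from optorho.stimulus import analytic_to_trace

K2 = 0.014
KOFF = 0.08


def step_trace(fold=2.0, t_end=120.0, dt=1.0):
    grid = np.arange(0.0, t_end + dt / 2, dt)
    return analytic_to_trace(step_input(fold, t_end), grid)


class TestRhoa:
    def test_rho_zero_step_matches_linear_closed_form(self):
        # dr/dt = k2 (g - r), g = 2 => r(t) = 2 - exp(-k2 t)
        r = simulate_rhoa(step_trace(), KineticParams(k2=K2, rho=0.0))
        assert r.value_at(60.0) == pytest.approx(2.0 - math.exp(-K2 * 60.0), abs=1e-6)

    def test_jump_map_across_instantaneous_pulse(self):
        # r+ = r- (1 + rho g-) / (1 + rho g+) = 2/3 for rho=1, g 1->2
        r = simulate_rhoa(step_trace(), KineticParams(k2=K2, rho=1.0))
        assert r.values[0] == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_jump_formula_matches_short_ramp_limit(self):
        # a 10 ms linear rise should reproduce the analytic jump to 1e-3
        p = PulseProtocol((10.0,), 2.0, 60.0)
        params = KineticParams(k2=K2, rho=1.5)
        r_jump = simulate_rhoa(simulate_recruitment(p, RecruitmentParams(20.0)), params)
        r_ramp = simulate_rhoa(
            simulate_recruitment(p, RecruitmentParams(20.0), rise_time=0.01), params
        )
        expected = pulse_jump_factor(1.5, 1.0, 2.0)
        assert r_jump.value_at(11.0) == pytest.approx(r_ramp.value_at(11.0), abs=1e-3)
        assert r_jump.values[np.searchsorted(r_jump.times, 10.0)] == pytest.approx(
            expected, abs=1e-6
        )

    @pytest.mark.parametrize("rho", [0.0, 0.5, 2.0])
    def test_constant_input_fixed_point_is_g(self, rho):
        # sequestration shapes transients only: r -> g-hat for any rho
        tr = step_trace(fold=1.8, t_end=5000.0, dt=5.0)
        r = simulate_rhoa(tr, KineticParams(k2=K2, rho=rho))
        assert r.values[-1] == pytest.approx(1.8, abs=1e-4)

    def test_convergence_rate_is_k2_over_one_plus_rho_g(self):
        # for constant g the main equation is linear with rate k2/(1+rho g)
        rho, ghat = 1.0, 2.0
        r = simulate_rhoa(step_trace(fold=ghat, t_end=400.0), KineticParams(k2=K2, rho=rho))
        rate = K2 / (1.0 + rho * ghat)
        r0 = r.values[0]
        expected = ghat + (r0 - ghat) * np.exp(-rate * r.times)
        assert np.allclose(r.values, expected, atol=1e-6)

    @settings(max_examples=10, deadline=None)
    @given(
        st.lists(st.integers(0, 199), min_size=1, max_size=5, unique=True),
        st.floats(0.0, 3.0),
    )
    def test_positivity_on_random_protocols(self, pulse_ints, rho):
        protocol = PulseProtocol(tuple(sorted(float(t) for t in pulse_ints)), 2.5, 200.0)
        g = simulate_recruitment(protocol, RecruitmentParams(20.0))
        sim = simulate_cell(g, KineticParams(k2=K2, rho=rho, koff_sensor=KOFF))
        for tr in (sim.r, sim.c, sim.b):
            assert np.all(tr.values > 0)


class TestCdc42:
    def test_equals_rhoa_at_rho_zero(self):
        g = step_trace()
        r = simulate_rhoa(g, KineticParams(k2=K2, rho=0.0))
        c = simulate_cdc42(g, KineticParams(k2=K2))
        assert np.allclose(r.values, c.values, atol=1e-7)

    def test_constant_input_stays_at_equilibrium(self):
        grid = np.arange(0.0, 100.0, 1.0)
        g = analytic_to_trace(step_input(1.0, 100.0), grid)
        c = simulate_cdc42(g, KineticParams(k2=K2))
        assert np.allclose(c.values, 1.0, atol=1e-12)

    def test_no_downward_jumps_under_pulsing(self, train30):
        # r jumps down at every pulse; c is continuous
        g = simulate_recruitment(train30, RecruitmentParams(20.0))
        params = KineticParams(k2=K2, rho=1.5, koff_sensor=KOFF)
        r = simulate_rhoa(g, params)
        c = simulate_cdc42(g, params)
        pulse_idx = np.searchsorted(g.times, train30.pulse_times)
        dr = np.diff(r.values)[pulse_idx[1:] - 1]
        dc = np.diff(c.values)[pulse_idx[1:] - 1]
        assert np.all(dr < 0)
        assert np.all(dc > -K2 * 1.5)  # bounded by the smooth ODE slope, no jumps


class TestBiosensor:
    def test_equilibrium_input_gives_flat_sensor(self):
        grid = np.arange(0.0, 50.0, 1.0)
        r = Trace(grid, np.ones_like(grid), channel="r")
        b = simulate_biosensor(r, KineticParams(koff_sensor=KOFF))
        assert np.allclose(b.values, 1.0)

    def test_step_response_closed_form(self):
        # db/dt = koff (r - b), r = 2 => b(t) = 2 - exp(-koff t)
        grid = np.arange(0.0, 40.25, 0.25)
        r = Trace(grid, np.full_like(grid, 2.0), channel="r")
        b = simulate_biosensor(r, KineticParams(koff_sensor=KOFF))
        assert b.value_at(12.5) == pytest.approx(2.0 - math.exp(-1.0), abs=1e-4)

    def test_sensor_dip_is_delayed_and_shallower_than_rhoa(self):
        g = step_trace(t_end=300.0)
        params = KineticParams(k2=K2, rho=1.0, koff_sensor=KOFF)
        r = simulate_rhoa(g, params)
        b = simulate_biosensor(r, params)
        assert b.values.min() > r.values.min()
        assert b.times[np.argmin(b.values)] > r.times[np.argmin(r.values)]

    def test_dip_then_rise_shape_at_high_expression(self, train30):
        # strong train, rho >= 1: the sensor first dips below baseline and
        # later rises above it
        g = simulate_recruitment(train30, RecruitmentParams(20.0))
        for rho in (1.0, 1.5):
            sim = simulate_cell(g, KineticParams(k2=K2, rho=rho, koff_sensor=KOFF))
            early = sim.b.values[sim.b.times <= 60.0]
            assert early.min() < 1.0
            assert sim.b.value_at(600.0) > 1.0


class TestFullModelOracle:
    def _full_params(self, rho, ratio, Kb=0.01):
        return FullModelParams(
            kon_bind=ratio * K2 / Kb, koff_bind=ratio * K2, Geq=rho * Kb, Req=1e-4 * Kb
        )

    def test_qssa_matches_mass_action_in_fast_binding_limit(self, train30):
        g = simulate_recruitment(train30, RecruitmentParams(20.0))
        rep = qssa_full_discrepancy(g, self._full_params(0.5, 100), K2)
        assert rep["sup_settled"] < 0.02

    def test_agreement_improves_with_binding_speed(self, train30):
        g = simulate_recruitment(train30, RecruitmentParams(20.0))
        sups = [
            qssa_full_discrepancy(g, self._full_params(0.5, ratio), K2)["sup_settled"]
            for ratio in (10, 100, 1000)
        ]
        assert sups[0] > sups[1] > sups[2]

    def test_negligible_sequestration_reproduces_linear_closed_form(self):
        g = step_trace(t_end=200.0)
        full = simulate_full(g, self._full_params(1e-4, 100), K2)
        expected = 2.0 - np.exp(-K2 * g.times)
        assert np.allclose(full.r.values, expected, atol=2e-3)

    def test_slow_binding_regime_is_reported_not_asserted(self, train30):
        # at koff_bind = k2 the QSSA premise fails; the discrepancy helper
        # documents the deviation in its report
        g = simulate_recruitment(train30, RecruitmentParams(20.0))
        rep = qssa_full_discrepancy(g, self._full_params(0.5, 1), K2)
        assert rep["binding_speed_ratio"] == pytest.approx(1.0)
        assert np.isfinite(rep["sup_settled"])
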