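"""Gating, HH current, GHK flux and calcium-step primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modvar.channels import (
    CalciumChannelSpec,
    CalciumDynamicsSpec,
    ChannelSpec,
    build_channel_specs,
    calcium_step,
    eval_gating,
    gate_step,
    ghk_calcium_current,
    hh_current,
)
from modvar.gates import GATES, logistic


def test_logistic_midpoint_and_symmetry():
    assert logistic(0.0) == 0.5
    for x in (-7.3, -1.0, 0.2, 12.0):
        assert logistic(x) + logistic(-x) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize(
    "channel,gate",
    [
        ("A", "m"), ("A", "h"), ("Ca", "m"), ("h", "m"), ("MI", "m"),
        ("Na", "m"), ("Na", "h"), ("K", "m"),
    ],
)
def test_voltage_gates_half_activate_at_their_midpoints(channel, gate):
    """Each sigmoidal voltage gate evaluates to 1/2 at its transcribed
    half-activation voltage (solved from the gating table)."""
    specs = build_channel_specs()
    spec = specs[channel]
    vhalf = GATES[channel][f"{gate}_vk"][0]
    fn = spec.m_inf if gate == "m" else spec.h_inf
    assert fn(vhalf, 0.02) == pytest.approx(0.5, abs=1e-12)


@given(
    v=st.floats(-120, 60),
    ca=st.floats(1e-6, 2.0),
    name=st.sampled_from(["A", "Ca", "h", "KCa", "MI", "Na", "K"]),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_gating_invariants_over_physiological_range(v, ca, name):
    """Steady states stay in [0,1] and time constants stay positive for
    all physiological voltages and calcium levels."""
    spec = build_channel_specs()[name]
    m_inf, tau_m, h_inf, tau_h = eval_gating(spec, v, ca)
    assert 0.0 <= m_inf <= 1.0
    assert 0.0 <= h_inf <= 1.0
    assert tau_m > 0
    assert tau_h > 0


def test_eval_gating_rejects_bad_inputs():
    spec = build_channel_specs()["A"]
    with pytest.raises(ValueError):
        eval_gating(spec, float("nan"), 0.02)
    with pytest.raises(ValueError):
        eval_gating(spec, -50.0, 0.0)


def test_hh_current_examples():
    spec = ChannelSpec("x", p=2, q=0, gbar=1.0, E=-60.0)
    # reversal potential
    assert hh_current(spec, 0.5, 1.0, -60.0) == 0.0
    # closed gate
    assert hh_current(spec, 0.0, 1.0, 0.0) == 0.0
    # arithmetic: 1 µS · 0.5² · 10 mV = 2.5 nA
    assert hh_current(spec, 0.5, 1.0, -50.0) == pytest.approx(2.5)
    with pytest.raises(ValueError):
        hh_current(spec, 1.5, 1.0, 0.0)


def test_gate_step_matches_exponential_relaxation():
    # fixed point
    assert gate_step(0.3, 0.3, 10.0, 0.5) == pytest.approx(0.3)
    # one-tau relaxation: z(τ) = 1 − e⁻¹
    z = 0.0
    for _ in range(1000):
        z = gate_step(z, 1.0, 10.0, 0.01)
    assert z == pytest.approx(1.0 - math.exp(-1.0), abs=1e-4)
    # multistep trajectory against the closed form
    z, worst = 0.2, 0.0
    for i in range(1, 2001):
        z = gate_step(z, 0.9, 7.0, 0.01)
        exact = 0.9 + (0.2 - 0.9) * math.exp(-i * 0.01 / 7.0)
        worst = max(worst, abs(z - exact))
    assert worst < 1e-4


def _ca_spec(P=1.0):
    return CalciumChannelSpec(P=P)


def test_ghk_closed_gate_and_removable_singularity():
    spec = _ca_spec()
    assert ghk_calcium_current(spec, 0.0, 1.0, -30.0, 0.02) == 0.0
    # two-sided numerical limit brackets the implemented v=0 value
    i_zero = ghk_calcium_current(spec, 1.0, 1.0, 0.0, 0.02)
    i_plus = ghk_calcium_current(spec, 1.0, 1.0, 1e-6, 0.02)
    i_minus = ghk_calcium_current(spec, 1.0, 1.0, -1e-6, 0.02)
    # the residual difference is the physical slope dI/dv times 2e-6 mV
    assert abs(i_plus - i_minus) < 2e-6
    assert i_zero == pytest.approx((i_plus + i_minus) / 2, abs=1e-9)


def test_ghk_inward_at_hyperpolarized_voltages():
    """With 13 mM external and trace internal calcium the current is
    inward (negative) for all v <= 0."""
    spec = _ca_spec()
    for v in np.linspace(-80.0, 0.0, 81):
        assert ghk_calcium_current(spec, 1.0, 1.0, float(v), 0.02) < 0


def test_ghk_rejects_nonpositive_calcium():
    with pytest.raises(ValueError):
        ghk_calcium_current(_ca_spec(), 1.0, 1.0, -30.0, 0.0)


def test_calcium_step_equilibrium_and_relaxation():
    spec = CalciumDynamicsSpec()  # ca_inf = 0.02 mM, tau = 25 ms
    assert calcium_step(0.02, 0.0, spec, 1.0) == pytest.approx(0.02)
    # closed-form relaxation from 0.04 mM over one time constant
    ca = 0.04
    for _ in range(2500):
        ca = calcium_step(ca, 0.0, spec, 0.01)
    assert ca == pytest.approx(0.02 + 0.02 * math.exp(-1.0), rel=1e-4)


def test_calcium_steady_state_above_rest_for_inward_current():
    """Constant inward (negative) calcium current raises the fixed point
    to ca_inf + τ·flux·|I|, found by iterating to convergence."""
    spec = CalciumDynamicsSpec()
    i_ca = -2.0
    expected = spec.ca_inf + spec.tau_ca * spec.flux * abs(i_ca)
    ca = spec.ca_inf
    for _ in range(10000):
        ca = calcium_step(ca, i_ca, spec, 0.1)
    assert ca == pytest.approx(expected, rel=1e-6)
    assert ca > spec.ca_inf


def test_calcium_step_flags_nonpositive_result():
    spec = CalciumDynamicsSpec(flux=10.0)
    with pytest.raises(ArithmeticError):
        calcium_step(0.001, 5.0, spec, 25.0)  # strong outward current
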