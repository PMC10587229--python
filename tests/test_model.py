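import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vazcycle.model import (
    GENOTYPES,
    InvalidStateError,
    KineticParameters,
    SystemState,
    apply_knockout,
    dark_steady_state,
    rate_equations,
    simulate,
    vde_activity,
)
from vazcycle.protocols import LightLevel, parse_protocol

REF = KineticParameters()


# ---------------------------------------------------------------------------
# Parameters and state containers
# ---------------------------------------------------------------------------

def test_parameter_round_trip():
    d = REF.to_dict()
    assert KineticParameters.from_dict(d) == REF


def test_parameter_validation_rejects_negative_rate():
    with pytest.raises(ValueError):
        KineticParameters(k_VA=-0.1)


def test_parameter_replace_returns_new_object():
    p2 = REF.replace(k_VA=0.2)
    assert p2.k_VA == 0.2
    assert REF.k_VA == 0.092


def test_state_round_trip_and_totals():
    ss = dark_steady_state(REF)
    arr = ss.as_array()
    assert SystemState.from_array(arr).as_array() == pytest.approx(arr)
    assert ss.protein_total == pytest.approx(REF.P_tot)
    assert ss.xanthophyll_total == pytest.approx(REF.X_tot)


def test_state_rejects_negative_concentration():
    ss = dark_steady_state(REF)
    arr = ss.as_array()
    arr[1] = -0.5
    with pytest.raises(InvalidStateError):
        SystemState.from_array(arr)


# ---------------------------------------------------------------------------
# Rate equations and conservation
# ---------------------------------------------------------------------------

def test_rate_equations_conserve_protein_and_pigment():
    ss = dark_steady_state(REF)
    # Perturb away from the steady state so the derivatives are non-trivial.
    arr = ss.as_array()
    arr[1] *= 0.8
    arr[3] += 0.2 * arr[1]
    dy = rate_equations(SystemState.from_array(arr), REF, LightLevel.HIGH)
    # d/dt (P + PV + PA + PZ + QV + QA + QZ) = 0
    assert dy[0] + dy[4:10].sum() == pytest.approx(0.0, abs=1e-12)
    # d/dt (V + A + Z + bound forms) = 0
    assert dy[1:10].sum() == pytest.approx(0.0, abs=1e-12)


def test_trajectory_conserves_totals():
    traj = simulate(parse_protocol("5HL-9D-5HL"), REF, output_dt=0.5)
    prot = traj.states[:, [0, 4, 5, 6, 7, 8, 9]].sum(axis=1)
    pig = traj.states[:, 1:10].sum(axis=1)
    assert np.all(np.abs(prot - REF.P_tot) < 1e-8)
    assert np.all(np.abs(pig - REF.X_tot) < 1e-8)


def test_example_epoxidation_rate_magnitude():
    """Under full VDE activity the V -> A step proceeds at k_VA = 0.092/min."""
    ss = dark_steady_state(REF)
    arr = ss.as_array()
    arr[-1] = 1.0  # alpha at its light maximum
    dy = rate_equations(SystemState.from_array(arr), REF, LightLevel.HIGH)
    state = SystemState.from_array(arr)
    # Net flux out of V: k_VA*alpha*V - k_AV*A (free pool only)
    expected = -(0.092 * 1.0 * state.V) + REF.k_AV * state.A \
        - REF.k_bind_f * state.P * state.V + REF.k_bind_b * state.PV
    assert dy[1] == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# VDE activity
# ---------------------------------------------------------------------------

def test_vde_activity_closed_form_light():
    # alpha(1 min HL) from 0: 1 - exp(-k_VDE_light)
    a = vde_activity(0.0, LightLevel.HIGH, REF, 1.0)
    assert a == pytest.approx(1.0 - math.exp(-1.3), rel=1e-12)


def test_vde_activity_relaxes_to_dark_maximum():
    a = vde_activity(1.0, LightLevel.DARK, REF, 1e4)
    assert a == pytest.approx(REF.alpha_max_dark, rel=1e-9)


@given(st.floats(min_value=0.0, max_value=1.0),
       st.floats(min_value=0.0, max_value=100.0))
def test_vde_activity_stays_in_unit_interval(alpha0, dt):
    for level in (LightLevel.HIGH, LightLevel.DARK):
        a = vde_activity(alpha0, level, REF, dt)
        assert -1e-12 <= a <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# Dark steady state
# ---------------------------------------------------------------------------

def test_dark_steady_state_has_zero_quenchers():
    ss = dark_steady_state(REF)
    assert ss.QV == 0.0 and ss.QA == 0.0 and ss.QZ == 0.0


def test_dark_steady_state_is_stationary():
    ss = dark_steady_state(REF)
    dy = rate_equations(ss, REF, LightLevel.DARK)
    assert np.max(np.abs(dy)) < 1e-8


def test_dark_steady_state_pool_ratios():
    """Flux balance fixes A/V = k_VA*alpha/k_AV and Z/A = k_AZ*alpha/k_ZA."""
    ss = dark_steady_state(REF)
    a = REF.alpha_max_dark
    assert ss.A / ss.V == pytest.approx(REF.k_VA * a / REF.k_AV, rel=1e-8)
    assert ss.Z / ss.A == pytest.approx(REF.k_AZ * a / REF.k_ZA, rel=1e-8)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def test_rk4_matches_adaptive_integrator():
    """Fixed-step and LSODA paths agree to well below measurement noise."""
    prot = parse_protocol("3HL-1D-1HL-3D-9HL-3D")
    t1 = simulate(prot, REF, method="adaptive", output_dt=0.5)
    t2 = simulate(prot, REF, method="rk4", rk4_dt=5e-3, output_dt=0.5)
    assert np.max(np.abs(t1.states - t2.states)) < 1e-5


def test_simulate_starts_from_dark_steady_state_by_default():
    traj = simulate(parse_protocol("1HL"), REF, output_dt=0.25)
    ss = dark_steady_state(REF)
    assert traj.states[0] == pytest.approx(ss.as_array(), abs=1e-10)


def test_quencher_equilibrium_approaches_capacity():
    """With interconversion frozen, QX/(PX+QX) -> K/(1+K) in the light."""
    frozen = REF.replace(k_VA=0.0, k_AZ=0.0, k_ZA=0.0, k_AV=0.0)
    traj = simulate(parse_protocol("30HL"), frozen, output_dt=1.0)
    end = traj.state_at(len(traj) - 1)
    for x, K in (("V", REF.K_QV_light), ("A", REF.K_QA_light), ("Z", REF.K_QZ_light)):
        px = getattr(end, "P" + x)
        qx = getattr(end, "Q" + x)
        if px + qx > 1e-9:
            assert qx / (px + qx) == pytest.approx(K / (1 + K), rel=1e-3)


def test_dark_phase_has_no_quenchers_at_equilibrium():
    """K_QX = 0 in darkness: quencher states fully relax back."""
    traj = simulate(parse_protocol("5HL-60D"), REF, output_dt=1.0)
    end = traj.state_at(len(traj) - 1)
    assert end.QV + end.QA + end.QZ < 1e-8


@settings(max_examples=10, deadline=None)
@given(st.integers(min_value=1, max_value=8))
def test_positivity_preserved(n_phases):
    phases = "-".join(("2HL" if i % 2 == 0 else "2D") for i in range(n_phases))
    traj = simulate(parse_protocol(phases), REF, output_dt=0.5)
    assert np.all(traj.states[:, :10] >= -1e-12)
    assert np.all((traj.states[:, 10] >= -1e-12) & (traj.states[:, 10] <= 1 + 1e-12))


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------

def test_genotype_list():
    assert set(GENOTYPES) == {"wild_type", "vde", "lhcx1", "vde_lhcx1"}


def test_vde_knockout_blocks_deepoxidation():
    p = apply_knockout(REF, "vde")
    traj = simulate(parse_protocol("10HL"), p, output_dt=1.0)
    end = traj.state_at(len(traj) - 1)
    start = traj.state_at(0)
    assert end.Z + end.PZ + end.QZ == pytest.approx(start.Z + start.PZ + start.QZ,
                                                    abs=1e-9)


def test_lhcx1_knockout_removes_protein_quenching():
    p = apply_knockout(REF, "lhcx1")
    traj = simulate(parse_protocol("10HL"), p, output_dt=1.0)
    assert np.all(traj.states[:, 4:10] == 0.0)


def test_unknown_genotype_raises():
    with pytest.raises(ValueError):
        apply_knockout(REF, "npq4")
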