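"""Pacemaker model dynamics: amplitude/phase definitions, light drive,
integrator correctness, and dark-attractor structure."""

import math
import warnings

import numpy as np
import pytest

import circamp as ca
from circamp.oscillators import dark_equilibrium_R, dark_period

TWO_PI = 2 * math.pi


# ---------------------------------------------------------------- amplitude

def test_amplitude_is_planar_norm_for_vdp(forger):
    assert ca.amplitude(forger, ca.VdPState(x=3.0, xc=4.0, n=0.0)) == pytest.approx(5.0)
    assert ca.amplitude(forger, ca.VdPState(x=0.0, xc=0.0, n=0.0)) == 0.0


def test_amplitude_is_R_for_hannay(hannay):
    assert ca.amplitude(hannay, ca.SPState(R=0.62, psi=1.0, n=0.0)) == 0.62


def test_state_type_must_match_model(forger, hannay):
    with pytest.raises(TypeError):
        ca.amplitude(forger, ca.SPState(R=0.5, psi=0.0, n=0.0))
    with pytest.raises(TypeError):
        ca.derivatives(hannay, ca.VdPState(x=1.0, xc=0.0, n=0.0), 0.0)


# -------------------------------------------------------------- phase angle

def test_phase_angle_conventions(forger, hannay):
    # anchor: positive-x axis is angle zero for the van der Pol family
    assert ca.phase_angle(forger, ca.VdPState(x=1.0, xc=0.0, n=0.0)) == pytest.approx(0.0)
    assert ca.phase_angle(hannay, ca.SPState(R=0.7, psi=1.2, n=0.0)) == pytest.approx(1.2)


def test_phase_angle_undefined_at_zero_amplitude(forger):
    with pytest.raises(ValueError, match="zero amplitude"):
        ca.phase_angle(forger, ca.VdPState(x=0.0, xc=0.0, n=0.0))


def test_phase_advances_one_turn_per_dark_period(any_spec):
    period = dark_period(any_spec)
    s = ca.limit_cycle_state(any_spec)
    traj = ca.integrate(any_spec, s, None, 0.0, 2 * period, 0.01)
    unwrapped = np.unwrap(traj.phase_angle)
    assert unwrapped[-1] - unwrapped[0] == pytest.approx(2 * TWO_PI, abs=0.05)


# -------------------------------------------------------------- light drive

def test_photic_drive_zero_in_darkness_and_at_full_activation(any_spec):
    if any_spec.is_vdp:
        state = ca.VdPState(x=0.5, xc=-0.5, n=0.3)
        saturated = ca.VdPState(x=0.5, xc=-0.5, n=1.0)
    else:
        state = ca.SPState(R=0.7, psi=1.0, n=0.3)
        saturated = ca.SPState(R=0.7, psi=1.0, n=1.0)
    assert ca.photic_drive(any_spec, state, 0.0) == 0.0
    assert ca.photic_drive(any_spec, saturated, 8000.0) == pytest.approx(0.0)
    with pytest.raises(ValueError, match=">= 0"):
        ca.photic_drive(any_spec, state, -1.0)


def test_process_l_drive_saturates_under_constant_light(any_spec):
    """From a dark-adapted state the photoreceptor drive peaks immediately
    and decays as the activated fraction n builds up."""
    s = ca.limit_cycle_state(any_spec)
    light = ca.LightSchedule(breakpoints=(0.0, 4.0), levels=(8000.0,))
    traj = ca.integrate(any_spec, s, light, 0.0, 4.0, 0.01)
    drive = np.array([ca.process_l_drive(any_spec, n, 8000.0) for n in traj.states[:, 2]])
    assert int(np.argmax(drive)) == 0  # dark-adapted: maximal response at onset
    assert drive[traj.index_of(3.0)] < drive.max()


# -------------------------------------------------------------- derivatives

def test_dark_fixed_points(forger, hannay):
    d = ca.derivatives(forger, ca.VdPState(x=0.0, xc=0.0, n=0.0), 0.0)
    assert np.all(d == 0.0)
    d = ca.derivatives(hannay, ca.SPState(R=0.0, psi=0.0, n=0.0), 0.0)
    assert d[0] == 0.0  # every dark R-term carries a factor R


def test_derivatives_match_integrator_finite_difference(any_spec):
    """Richardson-extrapolated finite differences of short integrator runs
    recover the analytic right-hand side to 1e-6."""
    state = ca.limit_cycle_state(any_spec, target_marker_phase=3.0)
    light = ca.LightSchedule(breakpoints=(0.0, 1.0), levels=(500.0,))
    y0 = state.as_array()
    delta = 1e-4
    d_big = (ca.integrate(any_spec, state, light, 0.0, delta, delta).states[-1] - y0) / delta
    d_small = (
        ca.integrate(any_spec, state, light, 0.0, delta / 2, delta / 2).states[-1] - y0
    ) / (delta / 2)
    fd = 2.0 * d_small - d_big
    expected = ca.derivatives(any_spec, state, 500.0)
    assert np.allclose(fd, expected, atol=1e-6)


# --------------------------------------------------------------- integrator

def test_integrate_zero_span_returns_initial_sample(forger):
    s = ca.VdPState(x=1.0, xc=0.5, n=0.1, t=2.0)
    traj = ca.integrate(forger, s, None, 2.0, 2.0, 0.01)
    assert len(traj) == 1
    assert np.allclose(traj.states[0], s.as_array())


def test_integration_is_bitwise_deterministic(any_spec):
    s = ca.limit_cycle_state(any_spec)
    light = ca.LightSchedule(breakpoints=(3.0, 9.0), levels=(500.0,))
    a = ca.integrate(any_spec, s, light, 0.0, 24.0, 0.05)
    b = ca.integrate(any_spec, s, light, 0.0, 24.0, 0.05)
    assert np.array_equal(a.states, b.states)


def test_photoreceptor_and_synchrony_stay_in_unit_interval(any_spec):
    s = ca.limit_cycle_state(any_spec)
    light = ca.LightSchedule(breakpoints=(0.0, 16.0), levels=(10000.0,))
    traj = ca.integrate(any_spec, s, light, 0.0, 48.0, 0.01)
    n = traj.states[:, 2]
    assert np.all((n >= 0.0) & (n <= 1.0))
    if not any_spec.is_vdp:
        R = traj.states[:, 0]
        assert np.all((R >= 0.0) & (R <= 1.0))


def test_integrator_is_fourth_order(forger):
    """Halving the step shrinks the endpoint error ~16x on a 24-h dark run."""
    s = ca.limit_cycle_state(forger)

    def endpoint(dt):
        return ca.integrate(forger, s, None, 0.0, 24.0, dt).states[-1]

    ref = endpoint(0.025)
    e1 = np.linalg.norm(endpoint(0.2) - ref)
    e2 = np.linalg.norm(endpoint(0.1) - ref)
    assert 8.0 <= e1 / e2 <= 32.0


def test_nonfinite_state_aborts_with_diagnostic(forger):
    wild = ca.VdPState(x=1e154, xc=1e154, n=0.0)
    with pytest.raises(FloatingPointError, match="non-finite"):
        ca.integrate(forger, wild, None, 0.0, 1.0, 0.1)


# ----------------------------------------------------------- dark attractor

def test_hannay_dark_R_converges_to_closed_form(hannay):
    traj = ca.integrate(hannay, ca.SPState(R=0.5, psi=0.0, n=0.0), None, 0.0, 600.0, 0.01)
    assert traj.states[-1, 0] == pytest.approx(dark_equilibrium_R(hannay), abs=1e-4)


def test_dark_free_run_recovers_nominal_period(any_spec):
    s = ca.limit_cycle_state(any_spec)
    traj = ca.integrate(any_spec, s, None, 0.0, 120.0, 0.01)
    spacing = np.diff(ca.circadian_markers(traj)["cbt_min_times"])
    assert np.allclose(spacing, dark_period(any_spec), atol=0.05)


def test_limit_cycle_state_is_at_cbtmin(forger):
    s = ca.limit_cycle_state(forger, target_marker_phase=0.0)
    # local minimum of x: near-zero x-velocity and x at its cycle minimum
    assert abs(ca.derivatives(forger, s, 0.0)[0]) < 5e-3
    traj = ca.integrate(forger, s, None, 0.0, 25.0, 0.01)
    assert s.x <= traj.states[:, 0].min() + 1e-3


def test_limit_cycle_state_burn_in_converged(any_spec):
    a = ca.limit_cycle_state(any_spec, 5.0, burn_in=240.0)
    b = ca.limit_cycle_state(any_spec, 5.0, burn_in=480.0)
    assert np.allclose(a.as_array(), b.as_array(), atol=1e-3)


def test_limit_cycle_state_repeatable(hannay):
    a = ca.limit_cycle_state(hannay, 2.0)
    b = ca.limit_cycle_state(hannay, 2.0)
    assert np.array_equal(a.as_array(), b.as_array())
    assert a.R == pytest.approx(dark_equilibrium_R(hannay), abs=1e-3)


# ------------------------------------------------------------------ markers

def test_markers_on_synthetic_cosine(forger):
    t = np.arange(0.0, 48.0001, 0.01)
    states = np.column_stack([np.cos(TWO_PI * t / 24.0), np.zeros_like(t), np.zeros_like(t)])
    traj = ca.Trajectory(model=forger, times=t, states=states)
    m = ca.circadian_markers(traj, dlmo_offset=0.0)
    assert m["cbt_min_times"] == pytest.approx([12.0, 36.0], abs=1e-6)
    assert m["dlmo_times"] == m["cbt_min_times"]  # identity offset
    m7 = ca.circadian_markers(traj, dlmo_offset=7.0)
    assert m7["dlmo_times"] == pytest.approx([5.0, 29.0], abs=1e-6)


def test_markers_warn_on_short_trajectory(forger):
    s = ca.limit_cycle_state(forger)
    traj = ca.integrate(forger, s, None, 0.0, 10.0, 0.01)
    with pytest.warns(UserWarning, match="less than one"):
        m = ca.circadian_markers(traj)
    assert m["cbt_min_times"] == []


# ------------------------------------------------------------ spec handling

def test_model_registry_and_validation():
    assert set(ca.registered_models()) == {"forger99", "jewett99", "hannay19_sp"}
    with pytest.raises(ValueError, match="registered models"):
        ca.get_model("forger2099")
    with pytest.raises(ValueError, match="tau"):
        ca.get_model("forger99", tau=-1.0)


def test_trajectory_csv_round_trip(tmp_path, hannay):
    s = ca.limit_cycle_state(hannay)
    traj = ca.integrate(hannay, s, None, 0.0, 5.0, 0.1)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["time_h", "R", "psi", "n", "amplitude", "phase_angle_rad"]
    assert np.allclose(df["R"], traj.states[:, 0])
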