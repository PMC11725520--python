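"""Phase and amplitude response curves to timed light pulses.

A response curve is built by paired simulation: starting from the dark
limit cycle, one run receives a light pulse at a given circadian phase
and a second identical run stays in darkness; the phase shift (hours,
advance positive) and percent amplitude change are read off at the
instant the pulse ends.  Scanning the pulse timing across the cycle
yields the phase response curve (PRC) and amplitude response curve (ARC).

Pulse timing is expressed in hours after CBTmin, and re-expressed
relative to DLMO (= CBTmin - ``dlmo_offset``), wrapped to (-12, 12].  A
free-run drift correction (the phase displacement a non-24-h clock
accumulates against wall time during the assessment interval) can be
subtracted from the PRC as a pure offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .light import PulseProtocol, PulseReference, pulse_schedule
from .oscillators import (
    DEFAULT_DLMO_OFFSET,
    DEFAULT_DT,
    ModelSpec,
    amplitude,
    dark_period,
    integrate,
    limit_cycle_state,
    phase_angle,
)

__all__ = [
    "StimulusResponse",
    "ResponseCurve",
    "phase_shift",
    "amplitude_change_pct",
    "scan_response",
    "free_run_drift",
    "apply_drift_correction",
    "dlmo_window",
]

TWO_PI = 2.0 * math.pi


def _wrap_half(hours: float, period: float = 24.0) -> float:
    """Wrap to the half-open interval (-period/2, period/2]."""
    w = hours % period
    if w > period / 2.0:
        w -= period
    return w


def phase_shift(spec: ModelSpec, state_stim, state_ref) -> float:
    """Phase shift in hours between paired states at the same instant,
    wrapped to (-12, 12], advances positive."""
    if abs(state_stim.t - state_ref.t) > 1e-9:
        raise ValueError("paired states must be at the same time")
    d = phase_angle(spec, state_stim) - phase_angle(spec, state_ref)
    return _wrap_half(d * 24.0 / TWO_PI)


def amplitude_change_pct(spec: ModelSpec, state_stim, state_ref) -> float:
    """Percent amplitude change ``100 (A_stim - A_ref) / A_ref``."""
    a_ref = amplitude(spec, state_ref)
    if a_ref <= 0:
        raise ValueError("reference amplitude is zero; percent change undefined")
    return 100.0 * (amplitude(spec, state_stim) - a_ref) / a_ref


@dataclass(frozen=True)
class StimulusResponse:
    pulse_phase_cbtmin: float  # h after CBTmin
    pulse_phase_dlmo: float  # h after DLMO, wrapped to (-12, 12]
    delta_phi: float  # h, advance positive
    pct_amp_change: float  # percent


@dataclass(frozen=True)
class ResponseCurve:
    """PRC + ARC on a grid of pulse timings for one model and protocol."""

    model_name: str
    protocol: PulseProtocol
    phases_cbtmin: np.ndarray
    phases_dlmo: np.ndarray
    delta_phi: np.ndarray
    pct_amp_change: np.ndarray
    drift_applied: float = 0.0
    dlmo_offset: float = DEFAULT_DLMO_OFFSET

    def __post_init__(self):
        for name in ("phases_cbtmin", "phases_dlmo", "delta_phi", "pct_amp_change"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.phases_cbtmin.size
        if any(
            getattr(self, name).size != n
            for name in ("phases_dlmo", "delta_phi", "pct_amp_change")
        ):
            raise ValueError("response-curve columns must have equal length")
        if n > 1 and not np.all(np.diff(self.phases_cbtmin) > 0):
            raise ValueError("grid phases must be strictly increasing")

    def __len__(self) -> int:
        return self.phases_cbtmin.size

    def __iter__(self):
        for i in range(len(self)):
            yield StimulusResponse(
                float(self.phases_cbtmin[i]),
                float(self.phases_dlmo[i]),
                float(self.delta_phi[i]),
                float(self.pct_amp_change[i]),
            )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "phase_rel_cbtmin_h": self.phases_cbtmin,
                "phase_rel_dlmo_h": self.phases_dlmo,
                "delta_phi_h": self.delta_phi,
                "pct_amp_change": self.pct_amp_change,
            }
        )

    def metadata(self) -> dict:
        return {
            "model": self.model_name,
            "protocol": {
                "duration_h": self.protocol.duration,
                "intensity_lux": self.protocol.intensity,
                "background_lux": self.protocol.background,
                "reference": self.protocol.reference,
            },
            "drift_applied_h": self.drift_applied,
            "dlmo_offset_h": self.dlmo_offset,
        }


def free_run_drift(spec: ModelSpec, interval: float) -> float:
    """Phase displacement (hours) of the dark free-running clock against a
    24.0-h clock over ``interval`` hours: ``interval * (24 - P) / P`` with
    ``P`` the model's dark free-running period.  Negative when the period
    exceeds 24 h."""
    if interval < 0:
        raise ValueError("interval must be >= 0")
    period = dark_period(spec)
    return interval * (24.0 - period) / period


def apply_drift_correction(curve: ResponseCurve, drift: float) -> ResponseCurve:
    """Subtract ``drift`` hours from every phase shift (a pure offset;
    amplitude values untouched); the accumulated correction is recorded in
    ``drift_applied``."""
    return replace(
        curve,
        delta_phi=curve.delta_phi - drift,
        drift_applied=curve.drift_applied + drift,
    )


def dlmo_window(dlmo_clock_h: float = 21.0) -> tuple:
    """The DLMO-8..DLMO-1 afternoon/evening window in clock hours (the
    candidate amplitude-boosting window; 13:00-20:00 for a 21:00 DLMO)."""
    return (dlmo_clock_h - 8.0, dlmo_clock_h - 1.0)


def scan_response(
    spec: ModelSpec,
    protocol: PulseProtocol,
    phase_grid=None,
    burn_in: float = 240.0,
    dt: float = DEFAULT_DT,
    dlmo_offset: float = DEFAULT_DLMO_OFFSET,
) -> ResponseCurve:
    """Build the PRC/ARC of ``protocol`` for ``spec``.

    For every grid phase (hours after CBTmin, default 0..23.5 in 0.5-h
    steps) the model is positioned on its dark attractor, run with and
    without the pulse, and the phase shift and percent amplitude change
    are evaluated exactly at the pulse-end sample.  Both runs share the
    time grid, so a zero-intensity pulse yields exact zeros.
    """
    if phase_grid is None:
        phase_grid = np.arange(0.0, 24.0, 0.5)
    phase_grid = np.asarray(phase_grid, dtype=float)

    period = dark_period(spec)
    s0 = limit_cycle_state(spec, 0.0, burn_in=burn_in, dt=dt)
    # dark reference spanning one period before the phase origin through
    # the latest pulse end; start rounded onto the integration grid
    t0 = -round(period / dt) * dt
    dur = protocol.duration
    t_max = float(phase_grid.max()) + dur
    s0.t = t0
    dark = integrate(spec, s0, None, t0, t_max, dt)

    half = dur / 2.0 if protocol.reference == PulseReference.pulse_center.value else 0.0
    shifts = np.empty(phase_grid.size)
    amps = np.empty(phase_grid.size)
    for i, phi in enumerate(phase_grid):
        start = float(phi) - half
        end = start + dur
        try:
            i_start = dark.index_of(start)
        except KeyError as exc:
            raise ValueError(
                f"pulse phase {phi} h does not align with the dt = {dt} grid"
            ) from exc
        light = pulse_schedule(protocol, float(phi) if half else start)
        # both arms restart from the same stored state so that a
        # zero-intensity pulse yields bitwise-identical runs (exact zeros)
        start_state = dark.state_at(i_start)
        stim = integrate(spec, start_state, light, start, end, dt)
        ref_state = integrate(spec, start_state, None, start, end, dt).final_state
        try:
            shifts[i] = phase_shift(spec, stim.final_state, ref_state)
            amps[i] = amplitude_change_pct(spec, stim.final_state, ref_state)
        except ValueError as exc:
            raise RuntimeError(f"response undefined at pulse phase {phi} h: {exc}")

    phases_dlmo = np.array(
        [_wrap_half(p + dlmo_offset) for p in phase_grid], dtype=float
    )
    return ResponseCurve(
        model_name=spec.name,
        protocol=protocol,
        phases_cbtmin=phase_grid,
        phases_dlmo=phases_dlmo,
        delta_phi=shifts,
        pct_amp_change=amps,
        drift_applied=0.0,
        dlmo_offset=dlmo_offset,
    )
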