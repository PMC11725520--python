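"""Actogram-shaped maps of instantaneous amplitude response to scheduled light.

For a sleep-wake schedule mapped to light (wake illuminance, darkness
during sleep), the pacemaker is entrained by simulating repeated average
days and then run through the schedule.  At every wake epoch the map
records the *instantaneous percent amplitude response* %dR:

    %dR = 100 * (Adot(state, I) - Adot(state, 0)) / A(state)

the percent-per-hour difference between the amplitude trend under the
scheduled illuminance and under darkness, evaluated at the current state.
Positive cells mean light at that moment is boosting amplitude, negative
cells mean suppression; sleep epochs are masked (flagged and exactly
zero, since in darkness the two trends coincide).  The day x time-of-day
matrix mirrors an actogram, making it easy to see how irregular sleep
lets waking light bleed into the suppression region around CBTmin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .light import light_from_sleepwake
from .oscillators import (
    ModelSpec,
    amplitude,
    derivatives,
    integrate,
    limit_cycle_state,
)
from .schedules import SleepWakeSchedule, regular_schedule

__all__ = [
    "AmplitudeResponseMap",
    "MapSummary",
    "instantaneous_amplitude_response",
    "build_map",
    "summarize_map",
    "render_actogram",
]

MAP_DT = 1.0 / 120.0  # h; two integration steps per minute-resolution epoch
DEFAULT_CBT_CLOCK = 4.0  # clock hour at which the pre-entrainment CBTmin sits


def instantaneous_amplitude_response(spec: ModelSpec, state, I: float) -> float:
    """Instantaneous %dR (percent per hour) of light level ``I`` vs darkness
    at the given state; exactly 0 for ``I = 0``."""
    a = amplitude(spec, state)
    if a <= 0:
        raise ValueError("amplitude response undefined at zero amplitude")
    if I == 0:
        return 0.0
    d_lit = derivatives(spec, state, I)
    d_dark = derivatives(spec, state, 0.0)
    if spec.is_vdp:
        adot_lit = (state.x * d_lit[0] + state.xc * d_lit[1]) / a
        adot_dark = (state.x * d_dark[0] + state.xc * d_dark[1]) / a
    else:
        adot_lit = d_lit[0]
        adot_dark = d_dark[0]
    return 100.0 * (adot_lit - adot_dark) / a


@dataclass(frozen=True)
class AmplitudeResponseMap:
    """Day x epoch matrix of %dR with a sleep mask (True = asleep/dark)."""

    model_name: str
    schedule: SleepWakeSchedule
    matrix: np.ndarray
    mask: np.ndarray
    wake_lux: float
    metadata: dict = field(default_factory=dict)
    trajectory: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        shape = (self.schedule.n_days, self.schedule.epochs_per_day)
        if m.shape != shape or mask.shape != shape:
            raise ValueError(f"matrix/mask must have shape {shape}")
        if np.any(m[mask] != 0.0):
            raise ValueError("masked (asleep) cells must carry %dR = 0")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "mask", mask)

    def to_frame(self):
        import pandas as pd

        epd = self.schedule.epochs_per_day
        idx = np.arange(self.matrix.size)
        return pd.DataFrame(
            {
                "day": idx // epd,
                "epoch_start_clock_h": (idx % epd) * self.schedule.epoch_hours,
                "state": self.schedule.states.astype(int),
                "pct_delta_R": self.matrix.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _mean_pattern(schedule: SleepWakeSchedule) -> tuple:
    """Circular-mean sleep onset clock hour and mean nightly duration."""
    s = schedule.states
    prev = np.roll(s, 1)
    onsets = np.nonzero((s == 1) & (prev == 0))[0]
    duration = 24.0 * schedule.sleep_fraction
    if onsets.size == 0:
        return 23.0, duration
    clock = (onsets % schedule.epochs_per_day) * schedule.epoch_hours
    ang = clock * 2.0 * np.pi / 24.0
    mean_ang = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return (mean_ang * 24.0 / (2.0 * np.pi)) % 24.0, duration


def build_map(
    spec: ModelSpec,
    schedule: SleepWakeSchedule,
    wake_lux: float = 500.0,
    burn_in_repeats: int = 14,
    dt: float = MAP_DT,
    cbt_clock: float = DEFAULT_CBT_CLOCK,
) -> AmplitudeResponseMap:
    """Entrain the model on the schedule's average day, then score %dR
    through the schedule's light.

    The burn-in simulates ``burn_in_repeats`` days of a regular schedule
    built from the mean sleep onset/duration, starting from the dark
    attractor with CBTmin placed at ``cbt_clock``.  Sleep epochs are
    masked and exactly zero.  Deterministic given its inputs.
    """
    if wake_lux < 0:
        raise ValueError("wake_lux must be >= 0")
    onset, duration = _mean_pattern(schedule)
    if not 0 < duration < 24:
        # degenerate all-sleep / all-wake schedule: no entrainable pattern
        burn_light = None
    else:
        burn_sched = regular_schedule(
            burn_in_repeats, onset, duration, schedule.epoch_minutes
        )
        burn_light = light_from_sleepwake(burn_sched, wake_lux=wake_lux).shifted(
            -24.0 * burn_in_repeats
        )
    main_light = light_from_sleepwake(schedule, wake_lux=wake_lux)
    light = burn_light.concatenated(main_light) if burn_light else main_light

    t0 = cbt_clock - 24.0 * burn_in_repeats
    t0 = round(t0 / dt) * dt
    s0 = limit_cycle_state(spec, 0.0)
    s0.t = t0
    t_end = 24.0 * schedule.n_days
    traj = integrate(spec, s0, light, t0, t_end, dt)

    epd = schedule.epochs_per_day
    ep_h = schedule.epoch_hours
    n = schedule.n_days * epd
    values = np.zeros(n)
    asleep = schedule.states == 1
    per_epoch = int(round(ep_h / dt))
    if abs(per_epoch * dt - ep_h) > 1e-9:
        raise ValueError(f"dt = {dt} h must divide the {schedule.epoch_minutes}-min epoch")
    offset = int(round(-t0 / dt))
    for i in range(n):
        if asleep[i]:
            continue
        state = traj.state_at(offset + i * per_epoch)
        values[i] = instantaneous_amplitude_response(spec, state, wake_lux)

    meta = {
        "model": spec.name,
        "wake_lux": wake_lux,
        "burn_in_repeats": burn_in_repeats,
        "dt_h": dt,
        "cbt_clock_h": cbt_clock,
        "normalization": (
            "pct_delta_R = 100 * (dA/dt under scheduled lux - dA/dt in darkness)"
            " / A(state), percent per hour, evaluated at each wake epoch start"
        ),
    }
    return AmplitudeResponseMap(
        model_name=spec.name,
        schedule=schedule,
        matrix=values.reshape(schedule.n_days, epd),
        mask=asleep.reshape(schedule.n_days, epd),
        wake_lux=wake_lux,
        metadata=meta,
        trajectory=traj,
    )


@dataclass(frozen=True)
class MapSummary:
    hours_boost: float
    hours_suppress: float
    integral_boost: float  # %dR * h, > 0
    integral_suppress: float  # %dR * h, < 0

    def as_dict(self) -> dict:
        return {
            "hours_boost": self.hours_boost,
            "hours_suppress": self.hours_suppress,
            "integral_boost": self.integral_boost,
            "integral_suppress": self.integral_suppress,
        }


def summarize_map(amap: AmplitudeResponseMap, days=None) -> MapSummary:
    """Totals of boosting/suppressing wake time and their %dR-hour
    integrals, optionally restricted to a subset of days."""
    m = amap.matrix if days is None else amap.matrix[days]
    ep_h = amap.schedule.epoch_hours
    pos = m > 0
    neg = m < 0
    return MapSummary(
        hours_boost=float(np.count_nonzero(pos)) * ep_h,
        hours_suppress=float(np.count_nonzero(neg)) * ep_h,
        integral_boost=float(np.sum(m[pos])) * ep_h,
        integral_suppress=float(np.sum(m[neg])) * ep_h,
    )


def render_actogram(amap: AmplitudeResponseMap, path, vmax: float = None) -> None:
    """Render the map as an actogram-style image: rows are days, blue =
    amplitude boosting, red = suppression, white = sleep."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.ma.masked_where(amap.mask, amap.matrix)
    if vmax is None:
        vmax = float(np.max(np.abs(amap.matrix))) or 1.0
    fig, ax = plt.subplots(figsize=(8, 0.35 * amap.schedule.n_days + 1.5))
    cmap = plt.get_cmap("RdBu").copy()
    cmap.set_bad("white")
    im = ax.imshow(
        data,
        aspect="auto",
        cmap=cmap,
        vmin=-vmax,
        vmax=vmax,
        extent=(0, 24, amap.schedule.n_days, 0),
        interpolation="nearest",
    )
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("day")
    ax.set_title(f"{amap.model_name}: instantaneous %dR at {amap.wake_lux:g} lux")
    fig.colorbar(im, ax=ax, label="%dR (percent / h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
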