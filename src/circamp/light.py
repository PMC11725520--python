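"""Piecewise-constant light schedules and stimulus protocols.

A :class:`LightSchedule` is a right-continuous step function of
illuminance: ``breakpoints`` (strictly increasing, hours) delimit
half-open intervals ``[b[i], b[i+1])`` carrying ``levels[i]`` lux, with a
``background`` level outside the listed span.  Protocol builders cover
the stimulus designs used in light-response experiments: a timed bright
pulse on a dark/dim background (constant routine), and the everyday light
pattern implied by a sleep-wake schedule (a configurable wake-time
illuminance, default 500 lux, darkness during sleep).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "LightSchedule",
    "PulseProtocol",
    "pulse_schedule",
    "light_from_sleepwake",
    "evaluate_light",
]


@dataclass(frozen=True)
class LightSchedule:
    breakpoints: tuple = ()
    levels: tuple = ()
    background: float = 0.0

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        lv = tuple(float(v) for v in self.levels)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)
        if bp and len(lv) != len(bp) - 1:
            raise ValueError("need exactly one level per interval between breakpoints")
        if not bp and lv:
            raise ValueError("levels given without breakpoints")
        if any(not math.isfinite(b) for b in bp):
            raise ValueError("breakpoints must be finite")
        if len(bp) > 1 and any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(v < 0 for v in lv) or self.background < 0:
            raise ValueError("illuminance levels must be >= 0")

    def shifted(self, delta: float) -> "LightSchedule":
        """Schedule translated in time by ``delta`` hours."""
        return LightSchedule(
            breakpoints=tuple(b + delta for b in self.breakpoints),
            levels=self.levels,
            background=self.background,
        )

    def concatenated(self, other: "LightSchedule") -> "LightSchedule":
        """Join two schedules whose spans abut (self ends where other starts)."""
        if not self.breakpoints:
            return other
        if not other.breakpoints:
            return self
        if abs(self.breakpoints[-1] - other.breakpoints[0]) > 1e-9:
            raise ValueError("schedules do not abut")
        return LightSchedule(
            breakpoints=self.breakpoints + other.breakpoints[1:],
            levels=self.levels + other.levels,
            background=self.background,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start_h": self.breakpoints[:-1],
                "end_h": self.breakpoints[1:],
                "lux": self.levels,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, background: float = 0.0) -> "LightSchedule":
        import pandas as pd

        df = pd.read_csv(path)
        if df.empty:
            return cls(background=background)
        starts = df["start_h"].to_numpy(dtype=float)
        ends = df["end_h"].to_numpy(dtype=float)
        lux = df["lux"].to_numpy(dtype=float)
        bp = [starts[0]]
        lv = []
        for s, e, v in zip(starts, ends, lux):
            if abs(s - bp[-1]) > 1e-9:
                # gap between rows: fill with background
                bp.append(s)
                lv.append(background)
            bp.append(e)
            lv.append(v)
        return cls(breakpoints=tuple(bp), levels=tuple(lv), background=background)


class PulseReference(str, Enum):
    pulse_center = "pulse_center"
    pulse_onset = "pulse_onset"


@dataclass(frozen=True)
class PulseProtocol:
    """A timed light pulse: ``duration`` hours at ``intensity`` lux on a
    constant ``background``, positioned by its center or onset."""

    duration: float
    intensity: float
    background: float = 0.0
    reference: str = "pulse_center"

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("pulse duration must be positive")
        if not (self.intensity >= self.background >= 0):
            raise ValueError("require intensity >= background >= 0")
        object.__setattr__(self, "reference", PulseReference(self.reference).value)


def pulse_schedule(protocol: PulseProtocol, t_ref: float) -> LightSchedule:
    """Light schedule for ``protocol`` positioned at ``t_ref`` hours.

    The pulse occupies the half-open interval ``[start, start + duration)``
    where ``start`` is ``t_ref`` (onset reference) or
    ``t_ref - duration/2`` (center reference).
    """
    if not math.isfinite(t_ref):
        raise ValueError("t_ref must be finite")
    start = t_ref
    if protocol.reference == PulseReference.pulse_center.value:
        start = t_ref - protocol.duration / 2.0
    return LightSchedule(
        breakpoints=(start, start + protocol.duration),
        levels=(protocol.intensity,),
        background=protocol.background,
    )


def light_from_sleepwake(schedule, wake_lux: float = 500.0, sleep_lux: float = 0.0) -> LightSchedule:
    """Map a sleep-wake schedule to light: ``wake_lux`` while awake,
    ``sleep_lux`` while asleep, background 0 outside the schedule span."""
    if wake_lux < 0 or sleep_lux < 0:
        raise ValueError("illuminance must be >= 0")
    states = np.asarray(schedule.states)
    if states.size == 0:
        raise ValueError("empty sleep-wake schedule")
    ep_h = schedule.epoch_minutes / 60.0
    lux = np.where(states == 1, sleep_lux, wake_lux)
    # merge runs of equal illuminance
    change = np.nonzero(np.diff(lux))[0] + 1
    starts = np.concatenate(([0], change))
    bp = [0.0] + [float(i * ep_h) for i in change] + [float(states.size * ep_h)]
    lv = [float(lux[i]) for i in starts]
    return LightSchedule(breakpoints=tuple(bp), levels=tuple(lv), background=0.0)


def evaluate_light(schedule: LightSchedule, t):
    """Illuminance at time(s) ``t`` (right-continuous lookup).

    Times before the first or at/after the last breakpoint evaluate to the
    background level.  Scalar in, scalar out; array in, array out.
    """
    scalar = np.isscalar(t)
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    bp = np.asarray(schedule.breakpoints, dtype=float)
    out = np.full(tt.shape, float(schedule.background))
    if bp.size >= 2:
        idx = np.searchsorted(bp, tt, side="right") - 1
        inside = (idx >= 0) & (idx < bp.size - 1)
        lv = np.asarray(schedule.levels, dtype=float)
        out[inside] = lv[idx[inside]]
    return float(out[0]) if scalar else out
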