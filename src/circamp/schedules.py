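"""Synthetic multi-day sleep-wake schedules and the Sleep Regularity Index.

Schedules are per-epoch binary sequences (1 = sleep, 0 = wake) over whole
days.  The Sleep Regularity Index (SRI) is the fraction of epoch pairs
exactly 24 h apart that share the same sleep/wake state, on a 0-1 scale
(the classical index spans -100..100; ``classical = 200 * fraction - 100``).

The generator produces a fixed nightly sleep window, optionally perturbed
day by day with independent uniform jitter on onset and duration; a
bisection routine calibrates the jitter magnitude so a generated schedule
realizes a requested SRI (e.g. the 0.75 "irregular sleeper" condition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SleepWakeSchedule",
    "regular_schedule",
    "jittered_schedule",
    "sleep_regularity_index",
    "calibrate_jitter",
    "CalibrationResult",
]

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class SleepWakeSchedule:
    """Binary sleep/wake sequence: ``epoch_minutes``-long epochs over
    ``n_days`` whole days; ``states[i] = 1`` means asleep."""

    epoch_minutes: int
    n_days: int
    states: np.ndarray

    def __post_init__(self):
        if MINUTES_PER_DAY % self.epoch_minutes != 0:
            raise ValueError("epoch_minutes must divide 1440")
        states = np.asarray(self.states, dtype=np.uint8)
        if not np.all((states == 0) | (states == 1)):
            raise ValueError("states must be binary (0 = wake, 1 = sleep)")
        expected = self.n_days * (MINUTES_PER_DAY // self.epoch_minutes)
        if states.size != expected:
            raise ValueError(
                f"expected {expected} epochs for {self.n_days} days, got {states.size}"
            )
        states.setflags(write=False)
        object.__setattr__(self, "states", states)

    @property
    def epochs_per_day(self) -> int:
        return MINUTES_PER_DAY // self.epoch_minutes

    @property
    def epoch_hours(self) -> float:
        return self.epoch_minutes / 60.0

    @property
    def sleep_fraction(self) -> float:
        return float(np.mean(self.states))

    def by_day(self) -> np.ndarray:
        """States reshaped to (n_days, epochs_per_day)."""
        return self.states.reshape(self.n_days, self.epochs_per_day)

    def to_frame(self):
        import pandas as pd

        epd = self.epochs_per_day
        idx = np.arange(self.states.size)
        return pd.DataFrame(
            {
                "day": idx // epd,
                "epoch_start_clock_h": (idx % epd) * self.epoch_hours,
                "state": self.states.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SleepWakeSchedule":
        import pandas as pd

        df = pd.read_csv(path)
        n_days = int(df["day"].max()) + 1
        epd = int((df["day"] == 0).sum())
        epoch_minutes = MINUTES_PER_DAY // epd
        df = df.sort_values(["day", "epoch_start_clock_h"])
        return cls(
            epoch_minutes=epoch_minutes,
            n_days=n_days,
            states=df["state"].to_numpy(),
        )


def _mark_windows(
    n_days: int, epoch_minutes: int, onsets_abs: np.ndarray, durations: np.ndarray
) -> np.ndarray:
    """Mark sleep epochs for per-day windows given in absolute hours.

    An epoch sleeps when its start time lies in a half-open window
    ``[onset, onset + duration)``; windows wrap circularly over the whole
    horizon, so sleep spilling past the final midnight lands on day 0.
    """
    ep_h = epoch_minutes / 60.0
    total = n_days * (MINUTES_PER_DAY // epoch_minutes)
    states = np.zeros(total, dtype=np.uint8)
    for onset, dur in zip(onsets_abs, durations):
        first = math.ceil(onset / ep_h - 1e-9)
        last = math.ceil((onset + dur) / ep_h - 1e-9)  # exclusive
        if last > first:
            states[np.arange(first, last) % total] = 1
    return states


def regular_schedule(
    n_days: int, onset_clock: float, duration: float, epoch_minutes: int = 1
) -> SleepWakeSchedule:
    """Perfectly periodic schedule: the same sleep window every day
    (onset at ``onset_clock`` hours after midnight, wrapping allowed)."""
    if not 0 < duration < 24:
        raise ValueError("sleep duration must lie strictly between 0 and 24 h")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    days = np.arange(n_days)
    onsets = 24.0 * days + (onset_clock % 24.0)
    durations = np.full(n_days, float(duration))
    states = _mark_windows(n_days, epoch_minutes, onsets, durations)
    return SleepWakeSchedule(epoch_minutes=epoch_minutes, n_days=n_days, states=states)


def jittered_schedule(
    n_days: int,
    onset_clock: float,
    duration: float,
    onset_jitter: float,
    duration_jitter: float,
    seed: int,
    epoch_minutes: int = 1,
) -> SleepWakeSchedule:
    """Schedule with per-day onset and duration perturbed by independent
    uniform draws on ``+-jitter``; reproducible given ``seed``.

    Durations pushed outside (0, 24) are clamped with a warning.  With both
    jitters zero this reproduces :func:`regular_schedule` exactly.
    """
    if onset_jitter < 0 or duration_jitter < 0:
        raise ValueError("jitters must be >= 0")
    if not 0 < duration < 24:
        raise ValueError("sleep duration must lie strictly between 0 and 24 h")
    rng = np.random.default_rng(seed)
    u_onset = rng.uniform(-1.0, 1.0, n_days)
    u_dur = rng.uniform(-1.0, 1.0, n_days)
    onsets_clock = (onset_clock % 24.0) + onset_jitter * u_onset
    durations = duration + duration_jitter * u_dur
    if np.any(durations <= 0) or np.any(durations >= 24):
        warnings.warn("jittered sleep duration clamped into (0, 24) h", stacklevel=2)
        durations = np.clip(durations, 0.01, 23.99)
    onsets_abs = 24.0 * np.arange(n_days) + onsets_clock
    states = _mark_windows(n_days, epoch_minutes, onsets_abs % (24.0 * n_days), durations)
    return SleepWakeSchedule(epoch_minutes=epoch_minutes, n_days=n_days, states=states)


def sleep_regularity_index(schedule: SleepWakeSchedule) -> float:
    """Fraction of epoch pairs 24 h apart in the same state (0-1 scale).

    The day lag is taken circularly over the recording (the final day is
    also compared with the first), which makes the index exactly invariant
    under circular time shifts and under sleep/wake complementation.  1.0
    means perfectly repeating days; the classical -100..100 index is
    ``200 * SRI - 100``.
    """
    if schedule.n_days < 2:
        raise ValueError("SRI requires at least 2 days")
    epd = schedule.epochs_per_day
    s = schedule.states
    return float(np.mean(s == np.roll(s, -epd)))


@dataclass(frozen=True)
class CalibrationResult:
    onset_jitter: float
    duration_jitter: float
    schedule: SleepWakeSchedule
    sri: float
    iterations: int


def calibrate_jitter(
    target_sri: float,
    tol: float = 0.01,
    seed: int = 0,
    max_iter: int = 60,
    *,
    n_days: int = 14,
    onset_clock: float = 23.0,
    duration: float = 8.0,
    epoch_minutes: int = 1,
    duration_jitter_ratio: float = 0.5,
) -> CalibrationResult:
    """Bisection over onset jitter until the generated schedule's SRI is
    within ``tol`` of ``target_sri``.

    The duration jitter is tied proportionally
    (``duration_jitter = duration_jitter_ratio * onset_jitter``).  The
    uniform deviates are drawn once from ``seed`` and rescaled, so the SRI
    is a deterministic, near-monotone function of the jitter magnitude and
    the returned jitter is reproducible for a fixed seed.
    """
    if not 0 < target_sri <= 1:
        raise ValueError("target_sri must lie in (0, 1]")
    if not tol > 0:
        raise ValueError("tol must be positive")

    def realize(j: float) -> SleepWakeSchedule:
        if j == 0.0:
            return regular_schedule(n_days, onset_clock, duration, epoch_minutes)
        return jittered_schedule(
            n_days,
            onset_clock,
            duration,
            onset_jitter=j,
            duration_jitter=duration_jitter_ratio * j,
            seed=seed,
            epoch_minutes=epoch_minutes,
        )

    def result(j, sched, sri, it):
        return CalibrationResult(
            onset_jitter=j,
            duration_jitter=duration_jitter_ratio * j,
            schedule=sched,
            sri=sri,
            iterations=it,
        )

    lo, hi = 0.0, 1.0
    sched = realize(lo)
    sri = sleep_regularity_index(sched)
    if abs(sri - target_sri) <= tol:
        return result(lo, sched, sri, 0)

    # expand the bracket until the SRI falls at or below the target
    it = 0
    while it < max_iter:
        it += 1
        sched = realize(hi)
        sri = sleep_regularity_index(sched)
        if sri <= target_sri:
            break
        hi *= 2.0
        if hi > 48.0:
            raise RuntimeError(
                f"could not bracket target SRI {target_sri}; best achieved {sri:.4f}"
            )
    if abs(sri - target_sri) <= tol:
        return result(hi, sched, sri, it)

    best = (abs(sri - target_sri), hi, sched, sri)
    while it < max_iter:
        it += 1
        mid = 0.5 * (lo + hi)
        sched = realize(mid)
        sri = sleep_regularity_index(sched)
        if abs(sri - target_sri) <= tol:
            return result(mid, sched, sri, it)
        if abs(sri - target_sri) < best[0]:
            best = (abs(sri - target_sri), mid, sched, sri)
        if sri > target_sri:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not reach SRI {target_sri} +- {tol} in {max_iter} "
        f"iterations; best achieved {best[3]:.4f} at jitter {best[1]:.3f} h"
    )
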