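"""Light:dark schedules for larval zebrafish experiments.

Larvae are typically raised and assayed on a 14:10 h light:dark cycle with
lights on at 9 a.m. and off at 11 p.m.; imaging experiments entrain on a
13:11 h cycle instead.  A :class:`LightSchedule` maps every minute of an
experiment to a ``day`` or ``night`` epoch, anchored to the recording start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

__all__ = ["LightSchedule", "Epoch"]

MIN_PER_DAY = 24 * 60


@dataclass(frozen=True)
class Epoch:
    """One contiguous day or night period within a recording.

    ``start_min``/``end_min`` form a half-open interval in minutes since the
    start of the recording.  ``calendar_day`` counts 24-h cycles from the
    recording start (0-based).
    """

    label: str  # "day" or "night"
    calendar_day: int
    start_min: int
    end_min: int

    @property
    def length_min(self) -> int:
        return self.end_min - self.start_min


@dataclass(frozen=True)
class LightSchedule:
    """A daily light:dark cycle.

    Parameters
    ----------
    lights_on, lights_off : float
        Time of day in hours at which white lights switch on and off.
        The default 9.0/23.0 gives the standard 14:10 rearing cycle;
        9.0/22.0 gives the 13:11 cycle used for imaging entrainment.
    n_days : int
        Number of 24-h cycles the schedule covers.
    """

    lights_on: float = 9.0
    lights_off: float = 23.0
    n_days: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.lights_on < 24.0 and 0.0 <= self.lights_off < 24.0):
            raise ValueError("lights_on/lights_off must be in [0, 24) h")
        if self.lights_on == self.lights_off:
            raise ValueError("day length must be positive (lights_on != lights_off)")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def day_hours(self) -> float:
        return (self.lights_off - self.lights_on) % 24.0

    @property
    def night_hours(self) -> float:
        return 24.0 - self.day_hours

    @property
    def total_minutes(self) -> int:
        return self.n_days * MIN_PER_DAY

    def is_day_at(self, hour_of_day: float) -> bool:
        """Whether white lights are on at a given time of day (hours)."""
        h = hour_of_day % 24.0
        on, off = self.lights_on, self.lights_off
        if on < off:
            return on <= h < off
        return h >= on or h < off

    def minute_labels(self, start_hour: float, n_minutes: int | None = None) -> np.ndarray:
        """Boolean day mask for each minute of a recording.

        Lights events are snapped to minute-bin boundaries anchored at the
        recording start (``start_hour``, time of day in hours).
        """
        if n_minutes is None:
            n_minutes = self.total_minutes
        if n_minutes <= 0:
            raise ValueError("n_minutes must be positive")
        if n_minutes > self.total_minutes:
            raise ValueError(
                f"schedule covers {self.total_minutes} min, requested {n_minutes}"
            )
        minutes = start_hour * 60.0 + np.arange(n_minutes)
        # snap each bin to its starting minute, evaluate mid-bin to avoid
        # float edge ambiguity at the exact lights transition
        hours = ((np.round(minutes) + 0.5) / 60.0) % 24.0
        on, off = self.lights_on, self.lights_off
        if on < off:
            return (hours >= on) & (hours < off)
        return (hours >= on) | (hours < off)

    def epochs(self, start_hour: float, n_minutes: int | None = None) -> List[Epoch]:
        """Maximal runs of constant light condition, in recording order."""
        is_day = self.minute_labels(start_hour, n_minutes)
        out: List[Epoch] = []
        boundaries = np.flatnonzero(np.diff(is_day.astype(int)))
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries + 1, [len(is_day)]))
        for s, e in zip(starts, ends):
            calendar_day = int((start_hour * 60.0 + s) // MIN_PER_DAY)
            out.append(
                Epoch(
                    label="day" if is_day[s] else "night",
                    calendar_day=calendar_day,
                    start_min=int(s),
                    end_min=int(e),
                )
            )
        return out
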