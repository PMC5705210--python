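"""Sleep/wake scoring of larval zebrafish videotracker activity.

The operational definitions implemented here are the standard larval
zebrafish ones: a movement is a pixel displacement between adjacent video
frames preceded and followed by >= 67 ms of inactivity; any one-minute bin
with no movement is one minute of sleep; a sleep bout is a maximal run of
consecutive sleep minutes; sleep latency is the time from a reference event
(lights on/off or heat shock) to the start of the first sleep bout; average
activity is seconds of movement per hour including sleep minutes, wake
activity the same excluding sleep minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .schedule import LightSchedule

__all__ = [
    "ActivityTrace",
    "BoutTable",
    "Latency",
    "detect_movement_events",
    "score_sleep",
    "extract_bouts",
    "sleep_latency",
    "activity_metrics",
    "epoch_metrics",
    "smooth_series",
    "normalize_to_control",
    "light_pulse_response",
    "ZERO_TOLERANCE",
]

#: A minute is sleep iff its seconds-of-movement is <= this (exact zero up to
#: float noise; the scoring rule is "no movement").
ZERO_TOLERANCE = 1e-9


@dataclass
class ActivityTrace:
    """One larva's per-minute activity (seconds of movement per 1-min bin)."""

    larva_id: str
    group: str
    start_hour: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values < 0) or np.any(self.values > 60):
            raise ValueError("per-minute activity must lie in [0, 60] s")

    @property
    def n_minutes(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BoutTable:
    """Half-open ``[start_min, end_min)`` intervals of consecutive sleep minutes."""

    starts: np.ndarray
    ends: np.ndarray

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def count(self) -> int:
        return int(self.starts.size)

    @property
    def total_sleep(self) -> int:
        return int(self.lengths.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start_min": self.starts, "end_min": self.ends})


class Latency(NamedTuple):
    """Sleep latency in minutes; ``censored`` marks epochs with no bout
    (latency then reports the remaining epoch length, not a missing value)."""

    minutes: float
    censored: bool


def detect_movement_events(
    displacements: Sequence[float], fps: float, min_gap_s: float = 0.067
) -> List[tuple]:
    """Group per-frame pixel displacements into movement events.

    A movement event is a maximal run of nonzero displacement; runs separated
    by less than ``min_gap_s`` of stillness merge into one event.  At 15 Hz a
    single still frame spans 66.7 ms < 67 ms and therefore does *not*
    separate events; two still frames (133 ms) do.

    Returns half-open ``(onset_frame, offset_frame)`` tuples.
    """
    disp = np.asarray(displacements, dtype=float)
    if disp.size == 0:
        raise ValueError("empty displacement series")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if np.any(disp < 0):
        raise ValueError("displacements must be >= 0")

    moving = disp > 0
    if not moving.any():
        return []
    diff = np.diff(moving.astype(int))
    onsets = list(np.flatnonzero(diff == 1) + 1)
    offsets = list(np.flatnonzero(diff == -1) + 1)
    if moving[0]:
        onsets.insert(0, 0)
    if moving[-1]:
        offsets.append(disp.size)

    events = [(onsets[0], offsets[0])]
    for on, off in zip(onsets[1:], offsets[1:]):
        gap_frames = on - events[-1][1]
        if gap_frames / fps < min_gap_s:
            events[-1] = (events[-1][0], off)
        else:
            events.append((on, off))
    return events


def score_sleep(trace, zero_tolerance: float = ZERO_TOLERANCE) -> np.ndarray:
    """Boolean sleep mask: one entry per minute, True where activity is zero."""
    values = trace.values if isinstance(trace, ActivityTrace) else np.asarray(trace, float)
    return values <= zero_tolerance


def extract_bouts(mask: Sequence[bool]) -> BoutTable:
    """Maximal runs of consecutive sleep minutes."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return BoutTable(np.empty(0, int), np.empty(0, int))
    diff = np.diff(m.astype(int))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    return BoutTable(starts.astype(int), ends.astype(int))


def sleep_latency(
    bouts: BoutTable, reference_min: float, epoch_end_min: Optional[float] = None
) -> Latency:
    """Minutes from a reference event to the start of the first sleep bout.

    A bout already ongoing at the reference gives latency 0.  If no bout
    starts at or after the reference, the latency is censored at the epoch
    end (``epoch_end_min`` required in that case).
    """
    ongoing = (bouts.starts <= reference_min) & (bouts.ends > reference_min)
    if ongoing.any():
        return Latency(0.0, False)
    after = bouts.starts[bouts.starts >= reference_min]
    if epoch_end_min is not None:
        after = after[after < epoch_end_min]
    if after.size:
        return Latency(float(after[0] - reference_min), False)
    if epoch_end_min is None:
        raise ValueError("no bout after reference and no epoch end to censor at")
    return Latency(float(epoch_end_min - reference_min), True)


def activity_metrics(values: Sequence[float], mask: Sequence[bool]) -> tuple:
    """(average_activity, wake_activity) in seconds per hour.

    Average activity includes sleep minutes; wake activity excludes them and
    is NaN when the larva never woke.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if v.shape != m.shape:
        raise ValueError("values and mask must be aligned")
    average = 60.0 * v.mean()
    wake = 60.0 * v[~m].mean() if (~m).any() else float("nan")
    return float(average), float(wake)


def epoch_metrics(trace: ActivityTrace, schedule: LightSchedule) -> pd.DataFrame:
    """Per-epoch sleep metrics for one larva.

    Bouts spanning an epoch boundary are split at the boundary for per-epoch
    sleep totals and bout lengths, and count once in each epoch they touch
    (splitting conserves total sleep).  Latency is measured from the epoch
    start and censored at the epoch end when the larva never slept in it.
    """
    mask = score_sleep(trace)
    bouts = extract_bouts(mask)
    epochs = schedule.epochs(trace.start_hour, trace.n_minutes)
    rows = []
    for ep in epochs:
        sel_start = np.maximum(bouts.starts, ep.start_min)
        sel_end = np.minimum(bouts.ends, ep.end_min)
        touching = sel_end > sel_start
        piece_lengths = (sel_end - sel_start)[touching]
        total_sleep = int(piece_lengths.sum())
        bout_count = int(touching.sum())
        mean_len = float(piece_lengths.mean()) if bout_count else float("nan")
        lat = sleep_latency(bouts, ep.start_min, ep.end_min)
        avg, wake = activity_metrics(
            trace.values[ep.start_min : ep.end_min], mask[ep.start_min : ep.end_min]
        )
        rows.append(
            {
                "larva_id": trace.larva_id,
                "group": trace.group,
                "label": ep.label,
                "calendar_day": ep.calendar_day,
                "start_min": ep.start_min,
                "end_min": ep.end_min,
                "total_sleep_min": total_sleep,
                "bout_count": bout_count,
                "mean_bout_length_min": mean_len,
                "latency_min": lat.minutes,
                "latency_censored": lat.censored,
                "average_activity_s_per_h": avg,
                "wake_activity_s_per_h": wake,
            }
        )
    return pd.DataFrame(rows)


def smooth_series(series: Sequence[float], window: int = 6) -> np.ndarray:
    """Centered moving mean used to display behavioral trends.

    With 10-min bins the default 6-point window spans 1 h.  For even window
    sizes the window covers ``[i - window//2, i + window//2 - 1]``; edges
    shrink to the available points (no padding).
    """
    x = np.asarray(series, dtype=float)
    if x.size < window:
        raise ValueError(f"need at least {window} points")
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def normalize_to_control(values: Sequence[float], control: Sequence[float]) -> np.ndarray:
    """Percent-of-control: ``100 * value / mean(control)`` per animal."""
    c = np.asarray(control, dtype=float)
    mean = c.mean()
    if not mean > 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * np.asarray(values, dtype=float) / mean


def light_pulse_response(
    traces: np.ndarray,
    onset_bin: int,
    pulse_min: int = 30,
    bin_s: float = 10.0,
    exclude_min: float = 1.0,
) -> np.ndarray:
    """Baseline-normalized activity during a light pulse (10-s binned data).

    For each larva the total activity during the pulse, excluding the first
    minute after onset, is divided by the group-mean baseline total over the
    matching pre-pulse window (``pulse_min`` before onset excluding the last
    minute).  The post-pulse lights-off burst is outside both windows and is
    ignored.  A genotype whose pulse activity matches baseline gives 1.

    ``traces`` is ``(n_larvae, n_bins)`` for one genotype.
    """
    x = np.atleast_2d(np.asarray(traces, dtype=float))
    bins_per_min = int(round(60.0 / bin_s))
    pulse_bins = pulse_min * bins_per_min
    excl = int(round(exclude_min * bins_per_min))
    if onset_bin < pulse_bins:
        raise ValueError(f"need {pulse_min} min of pre-pulse baseline")
    if onset_bin + pulse_bins > x.shape[1]:
        raise ValueError("trace ends before the pulse does")
    pulse_total = x[:, onset_bin + excl : onset_bin + pulse_bins].sum(axis=1)
    baseline_total = x[:, onset_bin - pulse_bins : onset_bin - excl].sum(axis=1)
    group_baseline = baseline_total.mean()
    if not group_baseline > 0:
        raise ValueError("group baseline activity must be > 0")
    return pulse_total / group_baseline
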