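"""Synthetic behavioral, tapping-assay and calcium-imaging data with known
ground truth.

Behavior is simulated as a two-state (wake/sleep) Markov chain per minute
with epoch-specific transition probabilities; wake minutes draw
seconds-of-movement from a gamma distribution truncated to [0, 60] (positive
and right-skewed, like real actigraphy), sleep minutes are exactly zero.
Heat-shock effects multiply the transition probabilities from heat-shock
onset with an exponentially decaying factor.  Tap responses follow the
variable-slope log-dose curve combined with background movement as a
probabilistic OR.  Calcium trials are 120 samples at 1 Hz with a flat
on-transient over 32-37 s, exponential habituation, and an off-transient
over 93-98 s.  Movies plant Gaussian-profile nuclei with independent
spike-and-decay traces.

All randomness uses NumPy's PCG64 ``default_rng``; each larva/animal owns a
stream seeded by ``(seed, group_index, larva_index)`` so datasets are
byte-identical for a fixed seed and adding animals never perturbs existing
ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .arousal import psychometric
from .config import SimConfig
from .schedule import LightSchedule
from .sleep import ActivityTrace

__all__ = [
    "gen_activity_traces",
    "gen_tap_dataset",
    "gen_trial_recordings",
    "gen_movie",
    "MovieTruth",
    "write_activity_csv",
    "read_activity_csv",
    "write_trials_csv",
    "read_trials_csv",
    "write_movie",
]


def _larva_rng(seed: int, group_index: int, larva_index: int) -> np.random.Generator:
    return np.random.default_rng((seed, group_index, larva_index))


# --------------------------------------------------------------------------
# behavior


def _truncated_gamma(rng, shape: float, scale: float, size: int) -> np.ndarray:
    x = rng.gamma(shape, scale, size=size)
    return np.clip(x, 0.0, 60.0)


def gen_activity_traces(
    config: SimConfig,
    schedule: LightSchedule,
    start_hour: float = 9.0,
    n_minutes: Optional[int] = None,
    initial_state: str = "stationary",
) -> List[ActivityTrace]:
    """Simulate per-minute activity traces for every larva of every group.

    ``initial_state`` is ``"stationary"`` (drawn from the stationary
    distribution of the first epoch's transition probabilities), ``"wake"``
    or ``"sleep"``.
    """
    if n_minutes is None:
        n_minutes = schedule.total_minutes
    if n_minutes <= 0:
        raise ValueError("duration must be positive")
    if initial_state not in ("stationary", "wake", "sleep"):
        raise ValueError(f"unknown initial_state: {initial_state!r}")

    is_day = schedule.minute_labels(start_hour, n_minutes)
    epochs = schedule.epochs(start_hour, n_minutes)
    min_since_epoch_start = np.empty(n_minutes)
    for ep in epochs:
        min_since_epoch_start[ep.start_min : ep.end_min] = (
            np.arange(ep.end_min - ep.start_min)
        )

    hs = config.heat_shock
    if hs.start_min is not None:
        t = np.arange(n_minutes, dtype=float)
        hs_decay = np.where(
            t >= hs.start_min,
            0.5 ** ((t - hs.start_min) / (hs.half_life_h * 60.0)),
            0.0,
        )
    else:
        hs_decay = np.zeros(n_minutes)

    traces: List[ActivityTrace] = []
    for gi, group in enumerate(config.groups):
        p_ws = np.where(
            is_day, group.p_wake_to_sleep["day"], group.p_wake_to_sleep["night"]
        ).astype(float)
        p_sw = np.where(
            is_day, group.p_sleep_to_wake["day"], group.p_sleep_to_wake["night"]
        ).astype(float)
        # heat-shock effect: multiplier decays from its peak toward 1
        p_ws = np.clip(p_ws * (1.0 + (group.hs_p_ws_mult - 1.0) * hs_decay), 0.0, 1.0)
        p_sw = np.clip(p_sw * (1.0 + (group.hs_p_sw_mult - 1.0) * hs_decay), 0.0, 1.0)
        if group.latency_shift > 0:
            p_ws = np.where(min_since_epoch_start < group.latency_shift, 0.0, p_ws)

        for li in range(config.n_larvae):
            rng = _larva_rng(config.seed, gi, li)
            u = rng.random(n_minutes)
            asleep = np.empty(n_minutes, dtype=bool)
            if initial_state == "stationary":
                denom = p_ws[0] + p_sw[0]
                pi_sleep = p_ws[0] / denom if denom > 0 else 0.0
                asleep[0] = u[0] < pi_sleep
            else:
                asleep[0] = initial_state == "sleep"
            for i in range(1, n_minutes):
                if asleep[i - 1]:
                    asleep[i] = not (u[i] < p_sw[i])
                else:
                    asleep[i] = u[i] < p_ws[i]
            activity = _truncated_gamma(
                rng, config.wake_gamma_shape, config.wake_gamma_scale, n_minutes
            )
            activity *= group.activity_multiplier
            activity = np.clip(activity, 0.0, 60.0)
            activity[asleep] = 0.0
            traces.append(
                ActivityTrace(
                    larva_id=f"{group.label}_{li:03d}",
                    group=group.label,
                    start_hour=start_hour,
                    values=activity,
                )
            )
    return traces


# --------------------------------------------------------------------------
# tapping assay


def gen_tap_dataset(config: SimConfig) -> pd.DataFrame:
    """Simulate the tapping assay for every larva of every group.

    Each larva receives ``len(powers) * trials_per_power`` stimuli (420 in
    the standard 14 x 30 design) in an order randomized per larva.  The
    response probability at power x is ``psi(x) + bg * (1 - psi(x))`` where
    ``psi`` is the variable-slope log-dose curve: a larva responds if the
    stimulus arouses it or if it happened to be moving anyway.

    Returns a tidy DataFrame (larva, group, power, trial, responded,
    pre_moved).
    """
    tap = config.tap
    powers = np.asarray(tap.powers, dtype=float)
    if np.any(powers <= 0):
        raise ValueError("tap powers must be > 0 (log-dose undefined)")
    psi = psychometric(powers, tap.bottom, tap.top, np.log10(tap.etp50), tap.hill)
    p_respond = np.minimum(1.0, psi + tap.background_move_prob * (1.0 - psi))

    frames = []
    for gi, group in enumerate(config.groups):
        for li in range(config.n_larvae):
            rng = _larva_rng(config.seed, gi, li)
            power_idx = np.repeat(np.arange(powers.size), tap.trials_per_power)
            rng.shuffle(power_idx)
            responded = rng.random(power_idx.size) < p_respond[power_idx]
            pre_moved = rng.random(power_idx.size) < tap.background_move_prob
            frames.append(
                pd.DataFrame(
                    {
                        "larva": f"{group.label}_{li:03d}",
                        "group": group.label,
                        "power": powers[power_idx],
                        "trial": np.arange(power_idx.size),
                        "responded": responded,
                        "pre_moved": pre_moved,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# calcium trials


@dataclass
class TrialRecordingSet:
    """Trial-structured fluorescence for one animal, ``traces`` is
    ``(n_trials, 120)`` at 1 Hz."""

    animal_id: str
    phase: str
    traces: np.ndarray


TRIAL_LEN_S = 120
LIGHT_ON_S = 32
LIGHT_OFF_S = 93
ON_WINDOW_END_S = 37
OFF_WINDOW_END_S = 98


def evoked_kernel(on_amplitude: float, off_amplitude: float, tau_s: float) -> np.ndarray:
    """Deterministic light-evoked component of a 120-s trial.

    Flat at ``on_amplitude`` over the 32-37 s on window, habituates
    exponentially until the light turns off, then flat at ``off_amplitude``
    over 93-98 s with the same habituation afterwards.  The 5-25 s intrinsic
    window is untouched, so at zero noise the 32-37 s window mean minus the
    intrinsic mean equals ``on_amplitude`` exactly.
    """
    t = np.arange(TRIAL_LEN_S, dtype=float)
    k = np.zeros(TRIAL_LEN_S)
    on = (t >= LIGHT_ON_S) & (t <= ON_WINDOW_END_S)
    k[on] = on_amplitude
    hab = (t > ON_WINDOW_END_S) & (t < LIGHT_OFF_S)
    k[hab] = on_amplitude * np.exp(-(t[hab] - ON_WINDOW_END_S) / tau_s)
    off = (t >= LIGHT_OFF_S) & (t <= OFF_WINDOW_END_S)
    k[off] = off_amplitude
    post = t > OFF_WINDOW_END_S
    k[post] = off_amplitude * np.exp(-(t[post] - OFF_WINDOW_END_S) / tau_s)
    return k


def gen_trial_recordings(
    config: SimConfig,
    n_trials: int,
    phase: str = "subjective_day",
    animal_id: str = "fish_000",
    reachr_suppression: bool = False,
    seed_offset: int = 0,
) -> TrialRecordingSet:
    """Simulate ``n_trials`` 2-min/1-Hz fluorescence trials for one animal.

    ``phase`` sets the intrinsic baseline (``subjective_day`` or
    ``subjective_night``).  With ``reachr_suppression`` the per-trial baseline
    decays from the day level toward a night-like level starting at the
    stimulation-onset trial, with an additive transient on that first
    stimulated trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if phase not in ("subjective_day", "subjective_night"):
        raise ValueError(f"unknown phase: {phase!r}")
    cal = config.calcium
    rng = np.random.default_rng((config.seed, 1_000_003, seed_offset))
    base = cal.day_baseline if phase == "subjective_day" else cal.night_baseline
    kernel = evoked_kernel(cal.on_amplitude, cal.off_amplitude, cal.habituation_tau_s)

    traces = np.empty((n_trials, TRIAL_LEN_S))
    for k in range(n_trials):
        level = base
        transient = 0.0
        if reachr_suppression and k >= cal.stim_onset_trial:
            dk = k - cal.stim_onset_trial
            level = cal.suppression_level + (base - cal.suppression_level) * np.exp(
                -dk / cal.suppression_tau_trials
            )
            if dk == 0:
                transient = cal.on_amplitude
        t = np.arange(TRIAL_LEN_S, dtype=float)
        trial = level + kernel + transient * np.exp(-t / 10.0)
        if cal.noise_sd > 0:
            trial = trial + rng.normal(0.0, cal.noise_sd, TRIAL_LEN_S)
        traces[k] = trial
    return TrialRecordingSet(animal_id=animal_id, phase=phase, traces=traces)


# --------------------------------------------------------------------------
# synthetic movies


@dataclass
class MovieTruth:
    """Planted ground truth returned alongside a synthetic movie."""

    centroids: np.ndarray  # (n_cells, 2) row/col
    masks: List[np.ndarray]  # boolean HxW, profile >= half max
    traces: np.ndarray  # (n_cells, n_frames)


def _place_cells(
    rng, n_cells: int, shape: Tuple[int, int], margin: float, min_sep: float
) -> np.ndarray:
    centroids = []
    attempts = 0
    limit = 20_000
    while len(centroids) < n_cells:
        attempts += 1
        if attempts > limit:
            raise ValueError(
                f"could not place {n_cells} cells with separation {min_sep} px "
                f"in a {shape[0]}x{shape[1]} frame"
            )
        c = margin + rng.random(2) * (np.array(shape) - 2 * margin)
        if all(np.hypot(*(c - p)) >= min_sep for p in centroids):
            centroids.append(c)
    return np.array(centroids).reshape(n_cells, 2)


def gen_movie(
    config: SimConfig,
    n_cells: int,
    frame_shape: Tuple[int, int] = (64, 64),
    n_frames: int = 200,
    seed_offset: int = 0,
) -> Tuple[np.ndarray, MovieTruth]:
    """Synthesize an imaging movie with planted active nuclei.

    Cells are Gaussian blobs of FWHM ``movie.cell_diameter_px`` with
    independent Bernoulli-spike traces convolved with an exponential decay
    (each cell is forced to spike at least once so every planted cell is
    active).  Ground-truth masks are the pixels at or above half the peak of
    each cell's spatial profile.

    Returns ``(stack, truth)`` with ``stack`` of shape
    ``(n_frames, *frame_shape)``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    mc = config.movie
    rng = np.random.default_rng((config.seed, 2_000_003, seed_offset))
    H, W = frame_shape
    margin = mc.cell_diameter_px
    # circle-packing bound: centers >= min_sep apart means disjoint
    # min_sep/2 radius disks around each center
    sep = max(mc.min_separation_px, 1.0)
    max_cells = int(
        (H - 2 * margin + sep) * (W - 2 * margin + sep) / (np.pi * (sep / 2.0) ** 2)
    )
    if n_cells > max_cells:
        raise ValueError(f"too many cells for frame area (max ~{max_cells})")

    sigma = mc.cell_diameter_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sigma
    yy, xx = np.mgrid[0:H, 0:W]

    stack = np.full((n_frames, H, W), mc.background_level, dtype=float)
    centroids = (
        _place_cells(rng, n_cells, (H, W), margin, mc.min_separation_px)
        if n_cells
        else np.empty((0, 2))
    )
    masks: List[np.ndarray] = []
    traces = np.zeros((n_cells, n_frames))
    decay = np.exp(-np.arange(n_frames) / mc.decay_tau_frames)
    for ci in range(n_cells):
        spikes = (rng.random(n_frames) < mc.spike_rate).astype(float)
        if not spikes.any():
            spikes[rng.integers(0, n_frames)] = 1.0
        tr = np.convolve(spikes, decay)[:n_frames]
        tr = mc.cell_amplitude * tr / tr.max()
        traces[ci] = tr
        cy, cx = centroids[ci]
        profile = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
        masks.append(profile >= 0.5)
        stack += tr[:, None, None] * profile[None, :, :]
    if mc.noise_sd > 0:
        stack += rng.normal(0.0, mc.noise_sd, stack.shape)
    return stack, MovieTruth(centroids=centroids, masks=masks, traces=traces)


# --------------------------------------------------------------------------
# on-disk formats (long-format CSV; multi-page TIFF; JSON sidecars)


def write_activity_csv(traces: Sequence[ActivityTrace], path) -> None:
    """Long-format activity table: (time_min, well, group, activity_s)."""
    frames = [
        pd.DataFrame(
            {
                "time_min": np.arange(t.n_minutes),
                "well": t.larva_id,
                "group": t.group,
                "activity_s": t.values,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_activity_csv(path, start_hour: float = 9.0) -> List[ActivityTrace]:
    df = pd.read_csv(path)
    traces = []
    for well, sub in df.groupby("well", sort=False):
        sub = sub.sort_values("time_min")
        traces.append(
            ActivityTrace(
                larva_id=str(well),
                group=str(sub["group"].iloc[0]),
                start_hour=start_hour,
                values=sub["activity_s"].to_numpy(),
            )
        )
    return traces


def write_trials_csv(recordings: Sequence[TrialRecordingSet], path) -> None:
    """Tidy trial table: (animal, phase, trial_idx, t_s, F)."""
    frames = []
    for rec in recordings:
        n_trials, n_s = rec.traces.shape
        frames.append(
            pd.DataFrame(
                {
                    "animal": rec.animal_id,
                    "phase": rec.phase,
                    "trial_idx": np.repeat(np.arange(n_trials), n_s),
                    "t_s": np.tile(np.arange(n_s), n_trials),
                    "F": rec.traces.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path) -> List[TrialRecordingSet]:
    df = pd.read_csv(path)
    out = []
    for (animal, phase), sub in df.groupby(["animal", "phase"], sort=False):
        n_trials = int(sub["trial_idx"].max()) + 1
        n_s = int(sub["t_s"].max()) + 1
        traces = (
            sub.sort_values(["trial_idx", "t_s"])["F"].to_numpy().reshape(n_trials, n_s)
        )
        out.append(TrialRecordingSet(str(animal), str(phase), traces))
    return out


def write_movie(stack: np.ndarray, truth: MovieTruth, out_dir) -> None:
    """Multi-page TIFF plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "movie.tif", stack.astype(np.float32))
    sidecar = {
        "centroids": truth.centroids.tolist(),
        "masks": [np.flatnonzero(m.ravel()).tolist() for m in truth.masks],
        "frame_shape": list(stack.shape[1:]),
        "traces": truth.traces.tolist(),
    }
    with open(out / "movie_truth.json", "w") as fh:
        json.dump(sidecar, fh)
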