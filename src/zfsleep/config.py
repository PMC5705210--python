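"""Ground-truth configuration for the synthetic data generators.

The defaults encode the study conditions the package emulates: 96-well
videotracker cohorts of 48 larvae per group on a 14:10 light:dark cycle,
a heat-shock-inducible sleep-promoting manipulation, the 14-power x 30-trial
tapping assay on the 0.01-40.95 solenoid power scale, and 2-min/1-Hz
trial-structured calcium recordings with light-onset and light-offset
evoked transients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

__all__ = [
    "GroupSpec",
    "HeatShock",
    "TapConfig",
    "CalciumConfig",
    "MovieConfig",
    "SimConfig",
    "default_tap_powers",
]


def default_tap_powers() -> List[float]:
    """14 tap intensities log-spaced over the 1-36.31 range of the 0.01-40.95
    solenoid power scale."""
    return [float(round(p, 2)) for p in np.logspace(0.0, np.log10(36.31), 14)]


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class GroupSpec:
    """One genotype/treatment group of the behavioral simulation.

    Transition probabilities are per-minute probabilities of the two-state
    (wake/sleep) Markov chain, specified separately for day and night.
    ``activity_multiplier`` scales the seconds-of-movement drawn for wake
    minutes.  ``latency_shift`` suppresses sleep onset for that many minutes
    after each epoch start (shifting sleep latency without changing the
    steady state).  ``hs_p_ws_mult``/``hs_p_sw_mult`` are the peak heat-shock
    effect multipliers applied to the transition probabilities from heat-shock
    onset, decaying with the configured half-life.
    """

    label: str
    activity_multiplier: float = 1.0
    p_wake_to_sleep: Dict[str, float] = field(
        default_factory=lambda: {"day": 0.01, "night": 0.07}
    )
    p_sleep_to_wake: Dict[str, float] = field(
        default_factory=lambda: {"day": 0.25, "night": 0.10}
    )
    latency_shift: float = 0.0
    hs_p_ws_mult: float = 1.0
    hs_p_sw_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.activity_multiplier <= 0:
            raise ValueError("activity_multiplier must be > 0")
        for epoch in ("day", "night"):
            _check_prob(f"p_wake_to_sleep[{epoch}]", self.p_wake_to_sleep[epoch])
            _check_prob(f"p_sleep_to_wake[{epoch}]", self.p_sleep_to_wake[epoch])
        if self.hs_p_ws_mult <= 0 or self.hs_p_sw_mult <= 0:
            raise ValueError("heat-shock multipliers must be > 0")
        if self.latency_shift < 0:
            raise ValueError("latency_shift must be >= 0")


@dataclass
class HeatShock:
    """Timing of the heat pulse that induces transgene overexpression.

    The behavioral effect is modeled as multipliers on the Markov transition
    probabilities (per group, see :class:`GroupSpec`) that start at
    ``start_min`` and decay exponentially with half-life ``half_life_h``,
    emulating declining levels of the overexpressed peptide.
    """

    start_min: Optional[int] = None  # None = no heat shock
    duration_min: int = 60
    half_life_h: float = 3.0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")


@dataclass
class TapConfig:
    """Ground truth of the mechano-acoustic tapping assay.

    ``bottom``/``top``/``etp50``/``hill`` parameterize the variable-slope
    log-dose response curve; ``background_move_prob`` is the per-trial
    probability of spontaneous movement in the 5 s before a stimulus.
    """

    powers: List[float] = field(default_factory=default_tap_powers)
    trials_per_power: int = 30
    bottom: float = 0.0
    top: float = 0.95
    etp50: float = 6.2
    hill: float = 1.8
    background_move_prob: float = 0.07

    def __post_init__(self) -> None:
        if len(self.powers) < 1 or any(p <= 0 for p in self.powers):
            raise ValueError("tap powers must be positive")
        if self.trials_per_power < 1:
            raise ValueError("trials_per_power must be >= 1")
        if not self.top > self.bottom and not (self.top == self.bottom == 0.0):
            raise ValueError("top must exceed bottom")
        if self.etp50 <= 0:
            raise ValueError("etp50 must be > 0")
        for name in ("bottom", "top", "background_move_prob"):
            _check_prob(name, getattr(self, name))


@dataclass
class CalciumConfig:
    """Ground truth of trial-structured (120 s at 1 Hz) calcium recordings.

    Intrinsic (pre-stimulus) fluorescence sits at a phase-dependent baseline;
    a light-on transient of amplitude ``on_amplitude`` starts at t = 32 s and
    an off transient of ``off_amplitude`` at t = 93 s, with exponential
    habituation (``habituation_tau_s``) between.  In suppression mode the
    per-trial baseline decays from the day level toward ``suppression_level``
    after the stimulation-onset trial (optogenetic silencing of activity
    toward a night-like level).
    """

    day_baseline: float = 100.0
    night_baseline: float = 75.0
    on_amplitude: float = 40.0
    off_amplitude: float = 30.0
    habituation_tau_s: float = 20.0
    suppression_level: float = 75.0
    suppression_tau_trials: float = 2.0
    stim_onset_trial: int = 5  # first stimulated trial, 0-based
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.day_baseline <= 0 or self.night_baseline <= 0:
            raise ValueError("baselines must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.habituation_tau_s <= 0 or self.suppression_tau_trials <= 0:
            raise ValueError("time constants must be > 0")


@dataclass
class MovieConfig:
    """Ground truth for small synthetic imaging movies.

    Cells are Gaussian-profile nuclei of nominal FWHM ``cell_diameter_px``
    (pixels stand in for the ~5 um nuclear diameter) with independent
    spike-and-decay activity traces on a constant background plus Gaussian
    noise.
    """

    cell_diameter_px: float = 5.0
    cell_amplitude: float = 50.0
    spike_rate: float = 0.05  # spikes per frame per cell
    decay_tau_frames: float = 8.0
    background_level: float = 10.0
    noise_sd: float = 0.5
    min_separation_px: float = 10.0

    def __post_init__(self) -> None:
        if self.cell_diameter_px <= 0:
            raise ValueError("cell_diameter_px must be > 0")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be >= 0")
        if not (0.0 < self.spike_rate <= 1.0):
            raise ValueError("spike_rate must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_groups() -> List[GroupSpec]:
    # Wild-type siblings and a heat-shock-inducible overexpression group.
    # The transgenic group's wake activity is reduced and its wake-to-sleep
    # transition strongly accelerated after heat shock, with a modest
    # lengthening of sleep bouts.
    return [
        GroupSpec(label="wt"),
        GroupSpec(
            label="hs_npvf",
            activity_multiplier=0.38,
            hs_p_ws_mult=27.0,
            hs_p_sw_mult=0.83,
        ),
    ]


@dataclass
class SimConfig:
    """Full generator ground truth; a fixed seed gives byte-identical output.

    RNG discipline: all draws use NumPy ``default_rng`` (PCG64).  Each larva
    owns an independent stream seeded by ``(seed, group_index, larva_index)``,
    so adding larvae or groups never perturbs existing ones.  Calcium and
    movie generators take explicit per-call seeds derived the same way.
    """

    n_larvae: int = 48
    groups: List[GroupSpec] = field(default_factory=_default_groups)
    heat_shock: HeatShock = field(default_factory=HeatShock)
    tap: TapConfig = field(default_factory=TapConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    movie: MovieConfig = field(default_factory=MovieConfig)
    wake_gamma_shape: float = 2.0
    wake_gamma_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if self.wake_gamma_shape <= 0 or self.wake_gamma_scale <= 0:
            raise ValueError("wake activity gamma parameters must be > 0")

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"unknown group label: {label!r}")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = [
                g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in d["groups"]
            ]
        for key, sub in (
            ("heat_shock", HeatShock),
            ("tap", TapConfig),
            ("calcium", CalciumConfig),
            ("movie", MovieConfig),
        ):
            if key in d and not isinstance(d[key], sub):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
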