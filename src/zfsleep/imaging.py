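"""Trial-structured calcium-imaging quantification and PCA/ICA segmentation.

Recordings are 2-min trials sampled at 1 Hz (120 samples): intrinsic
activity over 0-31 s, a light-on evoked response from t = 32 s, and a
light-off response from t = 93 s.  Phase-window means use the inclusive
integer-second windows 5-25 s (intrinsic), 32-37 s (on) and 93-98 s (off).
Several baseline (F0) and normalization (F_N) conventions are provided, and
active neurons are segmented from movies by PCA followed by spatial ICA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure
from sklearn.decomposition import PCA, FastICA

from .stats import t_test

__all__ = [
    "INTRINSIC_WINDOW",
    "ON_WINDOW",
    "OFF_WINDOW",
    "delta_f",
    "trial_window_means",
    "sliding_trial_smooth",
    "normalize",
    "f_n_post_light_peak",
    "evoked_intrinsic_correlation",
    "steady_state",
    "NeuronSet",
    "segment_neurons",
    "DayNightResult",
    "day_night_activity",
]

# inclusive integer-second windows within a 120-s trial
INTRINSIC_WINDOW = (5, 25)
ON_WINDOW = (32, 37)
OFF_WINDOW = (93, 98)


def _boxcar(x: np.ndarray, window: int) -> np.ndarray:
    return pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()


def delta_f(data, mode: str = "global_min", smooth_window_s: int = 5) -> np.ndarray:
    """Baseline-subtracted fluorescence, dF = F - F0.

    Modes
    -----
    ``global_min``
        F0 is the lowest signal over the whole recording, so min(dF) = 0.
    ``first5_mean``
        F0 is the mean over the first five trials; ``data`` must then be a
        2-D (n_trials, n_samples) array.
    ``smoothed_min_5s``
        The trace is smoothed with a centered 5-s boxcar and F0 is the
        minimum of the smoothed trace (the per-neuron convention).
    """
    x = np.asarray(data, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if mode == "global_min":
        return x - x.min()
    if mode == "first5_mean":
        if x.ndim != 2 or x.shape[0] < 5:
            raise ValueError("first5_mean needs >= 5 trials of samples")
        return x - x[:5].mean()
    if mode == "smoothed_min_5s":
        if x.ndim != 1 or x.size < smooth_window_s:
            raise ValueError("trace shorter than the smoothing window")
        return x - _boxcar(x, smooth_window_s).min()
    raise ValueError(f"unknown baseline mode: {mode!r}")


def _window_mean(samples: np.ndarray, window: Tuple[int, int]) -> float:
    lo, hi = window
    return float(samples[lo : hi + 1].mean())


def trial_window_means(samples: Sequence[float]) -> Tuple[float, float, float]:
    """(intrinsic, on-evoked, off-evoked) means of one 120-sample trial."""
    x = np.asarray(samples, dtype=float)
    if x.size <= OFF_WINDOW[1]:
        raise ValueError("trial too short for the 93-98 s window")
    return (
        _window_mean(x, INTRINSIC_WINDOW),
        _window_mean(x, ON_WINDOW),
        _window_mean(x, OFF_WINDOW),
    )


def sliding_trial_smooth(values: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving mean over trials, shrinking to available trials at the
    edges."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need >= 1 trial")
    return _boxcar(x, window)


def normalize(series, f_n: float) -> np.ndarray:
    """Divide a signal by a normalization constant F_N (> 0).

    F_N conventions: the mean intrinsic activity during subjective day, the
    per-animal peak after light onset (see :func:`f_n_post_light_peak`), or
    the per-animal day mean.
    """
    if not f_n > 0:
        raise ValueError("F_N must be > 0")
    return np.asarray(series, dtype=float) / f_n


def f_n_post_light_peak(traces: np.ndarray, light_on_s: int = 32) -> float:
    """Per-animal F_N: peak signal after the light turns on, across trials."""
    x = np.atleast_2d(np.asarray(traces, dtype=float))
    return float(x[:, light_on_s:].max())


def evoked_intrinsic_correlation(
    intrinsic: Sequence[float], evoked: Sequence[float]
) -> float:
    """Pearson correlation between per-trial intrinsic and evoked means."""
    x = np.asarray(intrinsic, float)
    y = np.asarray(evoked, float)
    if x.size < 3:
        raise ValueError("need >= 3 trials")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y)[0])


def steady_state(per_trial_values: Sequence[float]) -> float:
    """Mean of trials 10-15 (1-based, the last six of a 15-trial session)."""
    x = np.asarray(per_trial_values, dtype=float)
    if x.size < 15:
        raise ValueError("need >= 15 trials")
    return float(x[9:15].mean())


# --------------------------------------------------------------------------
# PCA/ICA segmentation


@dataclass
class NeuronSet:
    """Segmented ROIs with their traces and per-ROI baselines."""

    masks: List[np.ndarray]
    traces: np.ndarray  # (n_roi, n_frames), raw mean intensity over the mask
    f0: np.ndarray  # per-ROI baseline (smoothed-min rule)
    centroids: np.ndarray  # (n_roi, 2) row/col
    explained_variance_ratio: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )

    @property
    def n_neurons(self) -> int:
        return len(self.masks)

    def delta_f_traces(self) -> np.ndarray:
        return self.traces - self.f0[:, None]


def segment_neurons(
    movie: np.ndarray,
    n_pcs: int = 15,
    spatial_filter_px: float = 5.0,
    var_target: Optional[float] = None,
    threshold_sigma: float = 3.5,
    min_map_skewness: float = 1.0,
    random_state: int = 0,
) -> NeuronSet:
    """Segment active neurons from a movie by PCA followed by spatial ICA.

    The pixel-time matrix is reduced to ``n_pcs`` principal components (or,
    when ``var_target`` is given, to however many components cover that
    fraction of the signal variance).  FastICA then unmixes the retained
    spatial eigenmaps into independent spatial filters.  Each filter is
    sign-fixed to positive skewness and kept only if its skewness exceeds
    ``min_map_skewness`` (near-Gaussian maps carry no cells), then lightly
    smoothed at the expected cell scale and thresholded; connected regions
    whose half-peak (FWHM-style) blob has an equivalent diameter
    within [0.5, 2] x ``spatial_filter_px`` become candidate ROIs, and
    overlapping candidates from different filters are deduplicated by
    centroid distance.  ROI traces are mean movie intensity over the mask,
    with the smoothed-minimum baseline per ROI.

    Mean subtraction makes the output invariant to a constant intensity
    offset of every frame.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, H, W)")
    T, H, W = movie.shape
    if T < n_pcs:
        raise ValueError("movie must have at least n_pcs frames")
    X = movie.reshape(T, -1)
    if np.ptp(X) == 0:
        raise ValueError("degenerate (constant) movie")

    max_k = min(T - 1, X.shape[1])
    pca = PCA(n_components=min(max(n_pcs, 1), max_k), random_state=random_state)
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    if var_target is not None:
        k = int(np.searchsorted(np.cumsum(evr), var_target) + 1)
        k = min(max(k, 2), evr.size)
    else:
        k = min(n_pcs, evr.size)
    spatial_pcs = pca.components_[:k]  # (k, P)

    ica = FastICA(
        n_components=k,
        random_state=random_state,
        whiten="unit-variance",
        max_iter=2000,
        tol=1e-4,
    )
    # spatial ICA: pixels are samples, retained PCs are features
    maps = ica.fit_transform(spatial_pcs.T).T  # (k, P)

    sigma_px = spatial_filter_px / 6.0
    candidates = []  # (peak_weight, centroid, mask)
    d_lo, d_hi = 0.5 * spatial_filter_px, 2.0 * spatial_filter_px
    for comp in maps:
        img = comp.reshape(H, W)
        sk = stats.skew(img.ravel())
        if sk < 0:
            img, sk = -img, -sk
        # cell-bearing filters are strongly right-skewed (a compact bright
        # blob among background pixels); near-Gaussian maps are noise
        if sk < min_map_skewness:
            continue
        img = ndimage.gaussian_filter(img, sigma_px)
        thr = img.mean() + threshold_sigma * img.std()
        labels = measure.label(img > thr)
        for region in measure.regionprops(labels, intensity_image=img):
            # refine at half the regional peak (FWHM-style), keeping only the
            # connected blob containing the peak
            peak = float(region.intensity_max)
            ry, rx = np.unravel_index(
                np.argmax(np.where(labels == region.label, img, -np.inf)), img.shape
            )
            half_labels = measure.label(img >= 0.5 * peak)
            mask = half_labels == half_labels[ry, rx]
            eq_diam = 2.0 * np.sqrt(mask.sum() / np.pi)
            if not (d_lo <= eq_diam <= d_hi):
                continue
            w = img * mask
            total = w.sum()
            yy_c = (np.arange(H)[:, None] * w).sum() / total
            xx_c = (np.arange(W)[None, :] * w).sum() / total
            candidates.append((peak, np.array([yy_c, xx_c]), mask))

    candidates.sort(key=lambda c: -c[0])
    accepted: List[Tuple[np.ndarray, np.ndarray]] = []
    min_dist = 0.75 * spatial_filter_px
    for _, centroid, mask in candidates:
        if all(np.hypot(*(centroid - c)) >= min_dist for c, _ in accepted):
            accepted.append((centroid, mask))

    if not accepted:
        return NeuronSet(
            masks=[],
            traces=np.empty((0, T)),
            f0=np.empty(0),
            centroids=np.empty((0, 2)),
            explained_variance_ratio=evr[:k],
        )

    masks = [m for _, m in accepted]
    centroids = np.array([c for c, _ in accepted])
    traces = np.array([movie[:, m].mean(axis=1) for m in masks])
    f0 = np.array([_boxcar(tr, 5).min() for tr in traces])
    return NeuronSet(
        masks=masks,
        traces=traces,
        f0=f0,
        centroids=centroids,
        explained_variance_ratio=evr[:k],
    )


# --------------------------------------------------------------------------
# day/night comparisons


@dataclass
class DayNightResult:
    """Per-animal day/night activity summary.

    ``per_animal`` has one row per animal with its day mean (flanking day
    periods averaged), night mean and night/day ratio.  ``contrast`` is the
    mean fractional suppression at night (1 - night/day).  The one-sample
    t-test asks whether the night/day ratio differs from 1; the two-sample
    test compares ratios between the two groups when a ``group`` column is
    present.
    """

    per_animal: pd.DataFrame
    contrast: float
    one_sample: object
    two_sample: object = None


def day_night_activity(sessions: pd.DataFrame) -> DayNightResult:
    """Summarize per-session mean activity into day/night contrasts.

    ``sessions`` is tidy with columns ``animal``, ``period`` ("day"/"night";
    multiple day sessions, e.g. before and after the night, are averaged),
    ``value`` (mean dF over segmented neurons for that session) and
    optionally ``group``.
    """
    required = {"animal", "period", "value"}
    if not required.issubset(sessions.columns):
        raise ValueError(f"sessions needs columns {sorted(required)}")
    rows = []
    for animal, sub in sessions.groupby("animal", sort=False):
        day = sub.loc[sub["period"] == "day", "value"]
        night = sub.loc[sub["period"] == "night", "value"]
        if day.empty or night.empty:
            raise ValueError(f"animal {animal!r} is missing a day or night period")
        row = {
            "animal": animal,
            "day_mean": day.mean(),
            "night_mean": night.mean(),
        }
        row["night_day_ratio"] = row["night_mean"] / row["day_mean"]
        if "group" in sub.columns:
            row["group"] = sub["group"].iloc[0]
        rows.append(row)
    per_animal = pd.DataFrame(rows)
    ratios = per_animal["night_day_ratio"].to_numpy()
    contrast = float(1.0 - ratios.mean())
    one_sample = t_test(ratios, null_value=1.0) if ratios.size >= 2 else None
    two_sample = None
    if "group" in per_animal.columns:
        groups = per_animal["group"].unique()
        if groups.size == 2:
            a = per_animal.loc[per_animal["group"] == groups[0], "night_day_ratio"]
            b = per_animal.loc[per_animal["group"] == groups[1], "night_day_ratio"]
            if len(a) >= 2 and len(b) >= 2:
                two_sample = t_test(a.to_numpy(), b.to_numpy())
    return DayNightResult(
        per_animal=per_animal,
        contrast=contrast,
        one_sample=one_sample,
        two_sample=two_sample,
    )
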