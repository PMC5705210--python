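"""Arousal-threshold (tapping assay) analysis.

The assay delivers mechano-acoustic taps of graded power and records whether
each larva responds.  Per-power response fractions, corrected for the
background probability of spontaneous movement, are fit with the
variable-slope log-dose (four-parameter logistic) curve

    y(x) = bottom + (top - bottom) / (1 + 10**((logETP50 - log10(x)) * hill))

whose midpoint 10**logETP50 is the effective tap power 50 (ETP50): the
stimulus intensity producing a half-maximal response.  Groups are compared
with the extra-sum-of-squares F test on nested fits sharing all parameters
except logETP50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "psychometric",
    "PsychometricFit",
    "FComparison",
    "response_table",
    "background_probability",
    "adjust_fractions",
    "fit_psychometric",
    "etp50",
    "compare_fits_extra_ss",
    "percent_change",
]


def psychometric(
    power, bottom: float, top: float, log_etp50: float, hill: float
) -> np.ndarray:
    """Variable-slope log-dose response curve evaluated at ``power``."""
    x = np.asarray(power, dtype=float)
    if np.any(x <= 0):
        raise ValueError("power must be > 0 (log-dose undefined)")
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_etp50 - np.log10(x)) * hill))


@dataclass
class PsychometricFit:
    """Fitted variable-slope log-dose curve.

    ``degenerate`` marks fits on constant response fractions, where the
    midpoint and slope are undefined.
    """

    bottom: float
    top: float
    log_etp50: float
    hill: float
    ss_resid: float
    n_points: int
    df: int
    degenerate: bool = False

    def predict(self, power) -> np.ndarray:
        return psychometric(power, self.bottom, self.top, self.log_etp50, self.hill)


@dataclass
class FComparison:
    """Extra-sum-of-squares F test between nested psychometric fits."""

    f_statistic: float
    df1: int
    df2: int
    p_value: float
    ss_null: float
    ss_alt: float
    perfect_fit: bool = False


def response_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean response fraction per power (per group when present), powers
    ascending."""
    if trials.empty:
        raise ValueError("empty trial table")
    keys = ["group", "power"] if "group" in trials.columns else ["power"]
    out = (
        trials.groupby(keys, sort=True)["responded"]
        .mean()
        .rename("fraction")
        .reset_index()
    )
    return out


def background_probability(trials: pd.DataFrame):
    """Fraction of trials with movement in the 5 s before the stimulus.

    Returns a per-group Series when a ``group`` column is present, otherwise
    a float.
    """
    if "pre_moved" not in trials.columns or trials["pre_moved"].isna().any():
        raise ValueError("pre_moved must be recorded for all trials")
    if "group" in trials.columns:
        return trials.groupby("group")["pre_moved"].mean()
    return float(trials["pre_moved"].mean())


def adjust_fractions(fractions, background: float) -> np.ndarray:
    """Subtract the background movement probability, clamped to [0, 1].

    Fractions are probabilities, so the subtraction floors at 0.
    """
    if not (0.0 <= background <= 1.0):
        raise ValueError("background must be in [0, 1]")
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("fractions must be in [0, 1]")
    return np.clip(f - background, 0.0, 1.0)


_N_RESTARTS = 8


def _initial_guesses(
    log_x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> list:
    y_min, y_max = float(y.min()), float(y.max())
    mid = 0.5 * (y_min + y_max)
    log_e0 = float(log_x[np.argmin(np.abs(y - mid))])
    base = np.array([y_min, y_max, log_e0, 1.0])
    guesses = [base]
    span = log_x.max() - log_x.min()
    for _ in range(_N_RESTARTS):
        jitter = np.array(
            [
                0.1 * rng.standard_normal(),
                0.1 * rng.standard_normal(),
                0.5 * span * rng.standard_normal(),
                np.exp(rng.normal(0.0, 0.7)),
            ]
        )
        g = base + jitter * np.array([1.0, 1.0, 1.0, 0.0])
        g[3] = jitter[3]
        guesses.append(g)
    return guesses


def _ls_fit(residual_fn, x0, bounds) -> Tuple[np.ndarray, float]:
    x0 = np.clip(x0, bounds[0] + 1e-9, bounds[1] - 1e-9)
    res = optimize.least_squares(
        residual_fn, x0, bounds=bounds, method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return res.x, float(np.sum(res.fun**2))


def fit_psychometric(
    powers: Sequence[float],
    fractions: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> PsychometricFit:
    """Least-squares fit of the variable-slope log-dose curve.

    Unweighted least squares on per-power mean response fractions by default;
    optional weights multiply the residuals.  Bounds: bottom >= 0, top <= 1,
    hill unconstrained in sign.  Initialization is the data-driven guess plus
    8 deterministic jittered restarts; the lowest residual sum of squares
    wins.  Constant fractions give a flagged degenerate fit.
    """
    x = np.asarray(powers, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if x.shape != y.shape:
        raise ValueError("powers and fractions must be aligned")
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct powers to fit 4 parameters")
    if np.any(x <= 0):
        raise ValueError("powers must be > 0")
    w = np.ones_like(y) if weights is None else np.sqrt(np.asarray(weights, float))

    if np.ptp(y) == 0.0:
        return PsychometricFit(
            bottom=float(y[0]),
            top=float(y[0]),
            log_etp50=float("nan"),
            hill=float("nan"),
            ss_resid=0.0,
            n_points=y.size,
            df=y.size - 4,
            degenerate=True,
        )

    log_x = np.log10(x)
    span = log_x.max() - log_x.min()
    lo = np.array([0.0, 0.0, log_x.min() - 2.0 * span, -50.0])
    hi = np.array([1.0, 1.0, log_x.max() + 2.0 * span, 50.0])

    def residual(params):
        b, t, le, h = params
        return w * (psychometric(x, b, t, le, h) - y)

    rng = np.random.default_rng(0)
    best = None
    for guess in _initial_guesses(log_x, y, rng):
        try:
            params, ss = _ls_fit(residual, guess, (lo, hi))
        except Exception:
            continue
        if best is None or ss < best[1] - 1e-15:
            best = (params, ss)
    if best is None:
        raise RuntimeError("psychometric fit failed to converge from all starts")
    b, t, le, h = best[0]
    if b > t:  # equivalent reparametrization: swap plateaus, flip slope
        b, t, h = t, b, -h
    return PsychometricFit(
        bottom=float(b),
        top=float(t),
        log_etp50=float(le),
        hill=float(h),
        ss_resid=best[1],
        n_points=y.size,
        df=y.size - 4,
    )


def etp50(fit: PsychometricFit) -> float:
    """Effective tap power 50: the power at the curve's half-maximal point."""
    if fit.degenerate or not np.isfinite(fit.log_etp50):
        raise ValueError("ETP50 undefined for a degenerate fit")
    return float(10.0**fit.log_etp50)


def _joint_fit(
    log_x: np.ndarray,
    y: np.ndarray,
    group: np.ndarray,
    shared_midpoint: bool,
) -> Tuple[np.ndarray, float]:
    """Fit both groups with bottom/top/hill shared; logETP50 shared (null) or
    free per group (alternative)."""
    span = log_x.max() - log_x.min()
    le_lo, le_hi = log_x.min() - 2.0 * span, log_x.max() + 2.0 * span
    if shared_midpoint:
        lo = np.array([0.0, 0.0, le_lo, -50.0])
        hi = np.array([1.0, 1.0, le_hi, 50.0])
    else:
        lo = np.array([0.0, 0.0, le_lo, le_lo, -50.0])
        hi = np.array([1.0, 1.0, le_hi, le_hi, 50.0])

    x = 10.0**log_x

    def residual(params):
        if shared_midpoint:
            b, t, le, h = params
            pred = psychometric(x, b, t, le, h)
        else:
            b, t, le_a, le_b, h = params
            le = np.where(group == 0, le_a, le_b)
            pred = b + (t - b) / (1.0 + 10.0 ** ((le - log_x) * h))
        return pred - y

    y_min, y_max = float(y.min()), float(y.max())
    mid = 0.5 * (y_min + y_max)
    le0 = float(log_x[np.argmin(np.abs(y - mid))])
    rng = np.random.default_rng(1)
    if shared_midpoint:
        base = np.array([y_min, y_max, le0, 1.0])
    else:
        base = np.array([y_min, y_max, le0, le0, 1.0])
    guesses = [base]
    for _ in range(4):
        g = base.copy()
        g[2:-1] += 0.5 * span * rng.standard_normal(g.size - 3)
        g[-1] = np.exp(rng.normal(0.0, 0.7))
        guesses.append(g)
    best = None
    for guess in guesses:
        try:
            params, ss = _ls_fit(residual, guess, (lo, hi))
        except Exception:
            continue
        if best is None or ss < best[1] - 1e-15:
            best = (params, ss)
    if best is None:
        raise RuntimeError("joint psychometric fit failed to converge")
    return best


def compare_fits_extra_ss(
    powers_a: Sequence[float],
    fractions_a: Sequence[float],
    powers_b: Sequence[float],
    fractions_b: Sequence[float],
) -> FComparison:
    """Extra-sum-of-squares F test for a shared vs per-group ETP50.

    Null model: one curve with all four parameters shared.  Alternative:
    bottom, top and hill shared, logETP50 free per group.  The test therefore
    has df1 = 1 and df2 = n_total - 5.
    """
    xa = np.asarray(powers_a, float)
    xb = np.asarray(powers_b, float)
    ya = np.asarray(fractions_a, float)
    yb = np.asarray(fractions_b, float)
    log_x = np.log10(np.concatenate([xa, xb]))
    y = np.concatenate([ya, yb])
    group = np.concatenate([np.zeros(ya.size, int), np.ones(yb.size, int)])

    _, ss_null = _joint_fit(log_x, y, group, shared_midpoint=True)
    _, ss_alt = _joint_fit(log_x, y, group, shared_midpoint=False)
    ss_alt = min(ss_alt, ss_null)  # nested: guard optimizer noise

    df1 = 1
    df2 = y.size - 5
    if df2 < 1:
        raise ValueError("not enough points for the nested comparison")
    if ss_alt <= max(1e-12, 1e-12 * ss_null):  # perfect fit up to float noise
        return FComparison(
            f_statistic=float("inf"),
            df1=df1,
            df2=df2,
            p_value=float(np.nextafter(0.0, 1.0)),
            ss_null=ss_null,
            ss_alt=ss_alt,
            perfect_fit=True,
        )
    f_stat = ((ss_null - ss_alt) / df1) / (ss_alt / df2)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df1, df2))
    return FComparison(
        f_statistic=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p,
        ss_null=ss_null,
        ss_alt=ss_alt,
    )


def percent_change(etp50_treated: float, etp50_reference: float) -> int:
    """Signed percent change of ETP50 vs a reference, truncated toward zero.

    Truncation (227.4 -> 227, -46.8 -> -46) is the reporting convention for
    these percent changes.
    """
    if etp50_reference <= 0:
        raise ValueError("reference ETP50 must be > 0")
    return math.trunc(100.0 * (etp50_treated - etp50_reference) / etp50_reference)
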