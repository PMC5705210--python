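"""Group-comparison statistics and qPCR expression normalization.

Student's (pooled-variance) t-tests, one- and two-way ANOVA, Holm-Sidak
step-down multiple-comparison adjustment, Dunnett's many-to-one comparisons,
and relative expression by the delta-delta-Ct method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "t_test",
    "anova_oneway",
    "anova_twoway",
    "holm_sidak",
    "dunnett",
    "ddct",
]


@dataclass
class GroupSummary:
    """Mean +/- SEM convention for figure-style group summaries."""

    label: str
    n: int
    mean: float
    sem: float
    values: np.ndarray


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return GroupSummary(label=label, n=v.size, mean=float(v.mean()), sem=sem, values=v)


@dataclass
class TestResult:
    statistic: float
    df: float
    p_raw: float
    method: str
    p_adj: Optional[float] = None

    @property
    def p(self) -> float:
        return self.p_adj if self.p_adj is not None else self.p_raw


def t_test(
    a: Sequence[float],
    b: Optional[Sequence[float]] = None,
    null_value: float = 0.0,
    equal_var: bool = True,
) -> TestResult:
    """Two-tailed Student's t-test (pooled variance) or one-sample t-test.

    Zero variance with equal means returns t = 0, p = 1 by convention.
    Welch's form is available via ``equal_var=False``.
    """
    x = np.asarray(a, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if b is None:
        if np.ptp(x) == 0:
            p = 1.0 if x[0] == null_value else 0.0
            return TestResult(0.0 if x[0] == null_value else np.inf, x.size - 1, p,
                              "one-sample t-test")
        t, p = sps.ttest_1samp(x, null_value)
        return TestResult(float(t), x.size - 1, float(p), "one-sample t-test")
    y = np.asarray(b, dtype=float)
    if y.size < 2:
        raise ValueError("need n >= 2 per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        same = x[0] == y[0]
        return TestResult(
            0.0 if same else np.inf,
            x.size + y.size - 2,
            1.0 if same else 0.0,
            "Student's t-test" if equal_var else "Welch's t-test",
        )
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    df = (
        x.size + y.size - 2
        if equal_var
        else _welch_df(x, y)
    )
    return TestResult(
        float(t), float(df), float(p),
        "Student's t-test" if equal_var else "Welch's t-test",
    )


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    return (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))


def anova_oneway(*groups: Sequence[float]) -> TestResult:
    """One-way ANOVA; with two groups F equals the pooled t statistic squared."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 1 for g in gs):
        raise ValueError("need >= 2 groups, each with n >= 1")
    all_v = np.concatenate(gs)
    grand = all_v.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1 = len(gs) - 1
    df2 = all_v.size - len(gs)
    if df2 < 1:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(0.0, df1, 1.0, "one-way ANOVA")
        return TestResult(np.inf, df1, 0.0, "one-way ANOVA")
    f = (ss_between / df1) / (ss_within / df2)
    return TestResult(float(f), df1, float(sps.f.sf(f, df1, df2)), "one-way ANOVA")


def anova_twoway(data: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> Dict[str, TestResult]:
    """Two-way ANOVA with interaction.

    Assumes a (near-)balanced design, as in 96-well plate experiments;
    unbalanced input triggers a warning and Type-II sums of squares are used.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    if counts.min() < 1:
        raise ValueError("every factor-level combination needs n >= 1")
    if counts.nunique() > 1:
        warnings.warn("unbalanced design: using Type-II sums of squares")
    d = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    name_map = {"C(_a)": factor_a, "C(_b)": factor_b, "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    out = {}
    for row, nice in name_map.items():
        out[nice] = TestResult(
            statistic=float(table.loc[row, "F"]),
            df=float(table.loc[row, "df"]),
            p_raw=float(table.loc[row, "PR(>F)"]),
            method="two-way ANOVA",
        )
    return out


def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the original order.

    Sorted ascending, the i-th (1-based) p-value is adjusted to
    ``1 - (1 - p_i)**(m - i + 1)`` with a running maximum to preserve
    monotonicity, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty_like(p)
    adj[order] = np.clip(adj_sorted, 0.0, 1.0)
    return adj


def dunnett(
    treatments: List[Sequence[float]], control: Sequence[float]
) -> List[TestResult]:
    """Dunnett's many-to-one comparisons against a single control.

    Familywise error is controlled by the max-|t| null distribution under the
    Dunnett correlation structure (scipy's implementation).  With a single
    treatment the adjusted p-value reduces to the pooled two-sample t-test's.
    """
    c = np.asarray(control, dtype=float)
    if c.size < 2:
        raise ValueError("control needs n >= 2")
    if len(treatments) < 1:
        raise ValueError("need >= 1 treatment group")
    ts = [np.asarray(t, dtype=float) for t in treatments]
    res = sps.dunnett(*ts, control=c)
    n_total = c.size + sum(t.size for t in ts)
    df = n_total - (len(ts) + 1)
    out = []
    for stat, p in zip(np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
        out.append(
            TestResult(
                statistic=float(stat),
                df=float(df),
                p_raw=float(p),
                p_adj=float(p),
                method="Dunnett's test",
            )
        )
    return out


def ddct(
    ct_target: Sequence[float], ct_reference: Sequence[float]
) -> np.ndarray:
    """Relative expression by the delta-delta-Ct method.

    dCt = Ct_target - Ct_reference per sample; the calibrator is the sample
    with the highest target Ct (lowest expression, so the calibrator's
    relative expression is exactly 1 and everything else is >= 0 relative to
    it); relative expression = 2**(-(dCt - dCt_calibrator)).
    """
    tgt = np.asarray(ct_target, dtype=float)
    ref = np.asarray(ct_reference, dtype=float)
    if tgt.shape != ref.shape:
        raise ValueError("target and reference Ct arrays must be aligned")
    if not (np.isfinite(tgt).all() and np.isfinite(ref).all()):
        raise ValueError("Ct values must be finite")
    dct = tgt - ref
    calibrator = int(np.argmax(tgt))
    ddct_vals = dct - dct[calibrator]
    return 2.0 ** (-ddct_vals)
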