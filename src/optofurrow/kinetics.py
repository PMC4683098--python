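"""Recruitment/reversion kinetics fits and embryo-level statistics.

Kinetics are parameterized directly by half-times, matching how such
measurements are reported: recruitment follows
``R(t) = R_inf * (1 - 2**(-t / t_half))`` in cumulative illumination
time, reversion follows ``R(t) = R_0 * 2**(-t / t_half)`` in wall-clock
dark time.  Group comparisons use two-sided two-sample t tests
(pooled-variance Student's or Welch's) with optional log transform and
Bonferroni correction, on one summary value per embryo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticsFit",
    "StatResult",
    "fit_recruitment",
    "fit_reversion",
    "summarize_embryo",
    "compare_groups",
    "bonferroni",
]

#: convergence tolerance on the residual sum of squares
_RSS_TOL = 1e-8
#: minimal coefficient of determination below which a converged fit is
#: still flagged as a poor description of the data
_R2_GOOD = 0.8


@dataclass
class KineticsFit:
    """Result of a half-time kinetics fit.

    ``t_half`` is in the unit of the input time axis (seconds of
    illumination for recruitment, minutes of dark for reversion).
    ``converged`` means the optimizer succeeded on non-degenerate data;
    ``good_fit`` additionally requires the model to explain the data
    (R^2 >= 0.8), so a structurally wrong model is never silently
    accepted.
    """

    model: str  # 'recruitment' | 'reversion'
    plateau: float
    t_half: float
    baseline: float
    rss: float
    n_points: int
    converged: bool
    r_squared: float = float("nan")

    @property
    def good_fit(self) -> bool:
        return self.converged and self.r_squared >= _R2_GOOD

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        if self.model == "recruitment":
            return self.plateau * (1.0 - 2.0 ** (-t / self.t_half))
        return self.baseline * 2.0 ** (-t / self.t_half)


@dataclass
class StatResult:
    """Two-sample t-test result with optional Bonferroni correction."""

    group_names: tuple[str, str]
    test: str  # 'student_pooled' | 'welch'
    statistic: float
    df: float
    p: float
    p_adjusted: float
    correction: str  # 'none' | 'bonferroni'
    m_comparisons: int = 1
    degenerate: bool = False


def _fit_halftime(
    t: np.ndarray, y: np.ndarray, model: str
) -> KineticsFit:
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if len(t) < 3:
        raise ValueError("at least 3 points required")
    if np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ValueError("t must be non-negative and non-decreasing")

    n = len(t)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0 or np.allclose(y, y[0]):
        return KineticsFit(model, 0.0, float("nan"), float(y[0]), tss, n, False, 0.0)

    if model == "recruitment":
        def f(tt, amp, th):
            return amp * (1.0 - 2.0 ** (-tt / th))
        amp0 = float(np.max(np.abs(y)) * np.sign(y[np.argmax(np.abs(y))]))
    else:
        def f(tt, amp, th):
            return amp * 2.0 ** (-tt / th)
        amp0 = float(y[0]) if y[0] != 0 else float(np.max(np.abs(y)))

    span = max(t[-1] - t[0], np.min(np.diff(t)[np.diff(t) > 0], initial=1.0))
    # multi-start over a fixed half-time grid spanning the data range
    grid = np.geomspace(span / 100.0, span * 2.0, 7)
    best: tuple[float, np.ndarray] | None = None
    for th0 in grid:
        try:
            popt, _ = optimize.curve_fit(
                f,
                t,
                y,
                p0=[amp0, th0],
                bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - f(t, *popt)) ** 2))
        if best is None or rss < best[0] - _RSS_TOL:
            best = (rss, popt)
    if best is None:
        return KineticsFit(model, float("nan"), float("nan"), float("nan"), tss, n, False, 0.0)
    rss, (amp, th) = best
    r2 = 1.0 - rss / tss
    if model == "recruitment":
        return KineticsFit(model, float(amp), float(th), 0.0, rss, n, True, r2)
    return KineticsFit(model, 0.0, float(th), float(amp), rss, n, True, r2)


def fit_recruitment(t_exposure_s: np.ndarray, ratios: np.ndarray) -> KineticsFit:
    """Fit ``R = R_inf * (1 - 2**(-t/t_half))`` to a recruitment curve.

    ``t_exposure_s`` is cumulative illumination time in seconds;
    ``ratios`` are log2 pm/cyt values.  Returns the plateau and the
    illumination half-time; constant input is flagged degenerate
    (``converged = False``).
    """
    return _fit_halftime(t_exposure_s, ratios, "recruitment")


def fit_reversion(t_dark_min: np.ndarray, ratios: np.ndarray) -> KineticsFit:
    """Fit ``R = R_0 * 2**(-t/t_half)`` to a dark-reversion curve.

    ``t_dark_min`` is time since the end of illumination, in minutes.
    """
    return _fit_halftime(t_dark_min, ratios, "reversion")


def summarize_embryo(
    features: pd.DataFrame, variable: str, by: tuple[str, ...] = ("embryo_id", "t_index")
) -> pd.DataFrame:
    """Per-(embryo, t) median, interquartile range and cell count.

    The IQR is Q3 - Q1 with linear-interpolation quantiles.
    """
    if len(features) == 0:
        raise ValueError("empty feature table")
    if variable not in features.columns:
        raise KeyError(f"no column {variable!r}")

    def _agg(s: pd.Series) -> pd.Series:
        v = s.dropna().to_numpy(dtype=np.float64)
        if v.size == 0:
            raise ValueError("no values to summarize")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return pd.Series({"median": med, "iqr": q3 - q1, "n_cells": v.size})

    out = features.groupby(list(by), sort=True)[variable].apply(_agg).unstack()
    out["n_cells"] = out["n_cells"].astype(int)
    return out.reset_index()


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p value, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def compare_groups(
    group_a: np.ndarray,
    group_b: np.ndarray,
    test: str = "student_pooled",
    log_transform: bool = False,
    m_comparisons: int = 1,
    names: tuple[str, str] = ("a", "b"),
) -> StatResult:
    """Two-sided two-sample t test on embryo-level summary values.

    ``test`` selects pooled-variance Student's (df = n1 + n2 - 2) or
    Welch's (Welch-Satterthwaite df).  With ``log_transform`` the test
    runs on natural-log values (for positively skewed quantities such
    as cell areas; the t statistic is base-invariant).  Bonferroni
    correction multiplies p by ``m_comparisons`` and caps at 1.  Two
    constant, equal groups yield t = 0, p = 1, flagged degenerate.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if test not in ("student_pooled", "welch"):
        raise ValueError("test must be 'student_pooled' or 'welch'")
    if log_transform:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log transform requires positive values")
        a, b = np.log(a), np.log(b)

    degenerate = False
    if np.var(a) == 0 and np.var(b) == 0:
        degenerate = True
        if a.mean() == b.mean():
            stat, p, df = 0.0, 1.0, len(a) + len(b) - 2
        else:
            stat = np.inf if a.mean() > b.mean() else -np.inf
            p, df = 0.0, len(a) + len(b) - 2
    else:
        res = stats.ttest_ind(a, b, equal_var=(test == "student_pooled"))
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)

    correction = "bonferroni" if m_comparisons > 1 else "none"
    return StatResult(
        group_names=names,
        test=test,
        statistic=float(stat),
        df=float(df),
        p=float(p),
        p_adjusted=bonferroni(float(p), m_comparisons),
        correction=correction,
        m_comparisons=m_comparisons,
        degenerate=degenerate,
    )
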