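"""Internalization ratios, expression filtering, summaries and t-tests.

The per-cell internalization ratio QD_interior / (QD_interior + QD_membrane)
is an internally calibrated measure: any common gain applied to both
compartment sums (amplifier gain, zoom factor) cancels.  Cells are filtered
to a similar receptor-expression range (over-expression alters
internalization rates), summarized as mean +- s.e.m. per ligand x time, and
ligands are compared per timepoint with two-tailed Student's t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InternalizationMeasurement",
    "TestResult",
    "internalization_ratio",
    "measurements_to_frame",
    "filter_by_expression",
    "summarize_timepoints",
    "t_test_two_sample",
    "t_test_from_summary",
]


@dataclass
class InternalizationMeasurement:
    """Per-cell compartment sums and derived quantities."""

    field_id: str
    cell_id: str
    ligand: str
    time_min: float
    qd_membrane_sum: float
    qd_interior_sum: float
    membrane_px: int
    interior_px: int
    cell_px: int
    syfp_mean: float
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def qd_total(self) -> float:
        return self.qd_membrane_sum + self.qd_interior_sum

    @property
    def ratio(self) -> float:
        return internalization_ratio(self)


def internalization_ratio(m: InternalizationMeasurement) -> float:
    """QD_interior / QD_total for one cell; requires QD signal present."""
    total = m.qd_total
    if total <= 0:
        raise ValueError("no QD signal: ratio undefined (cell should be excluded)")
    return m.qd_interior_sum / total


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Tidy per-cell table; excluded cells keep NaN ratios."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "field_id": m.field_id,
                "cell_id": m.cell_id,
                "ligand": m.ligand,
                "time_min": m.time_min,
                "qd_membrane_sum": m.qd_membrane_sum,
                "qd_interior_sum": m.qd_interior_sum,
                "qd_total": m.qd_total,
                "ratio": m.qd_interior_sum / m.qd_total if m.qd_total > 0 else np.nan,
                "membrane_px": m.membrane_px,
                "interior_px": m.interior_px,
                "cell_px": m.cell_px,
                "syfp_mean": m.syfp_mean,
                "excluded": m.excluded,
                "exclusion_reason": m.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


def filter_by_expression(frame: pd.DataFrame, fold_window: float = 2.0):
    """Retain cells with receptor expression within a fold window of the median.

    The window is [median/fold_window, median*fold_window] of ``syfp_mean``
    over all non-excluded cells in the experiment.  Returns
    ``(retained, exclusion_log)``; the log lists each dropped cell with its
    expression value and the window, so the filter is auditable.
    """
    if fold_window < 1:
        raise ValueError("fold_window must be >= 1")
    if frame.empty:
        return frame.copy(), pd.DataFrame(columns=["field_id", "cell_id", "syfp_mean", "lo", "hi"])
    pool = frame.loc[~frame["excluded"], "syfp_mean"]
    med = float(pool.median()) if len(pool) else float("nan")
    lo, hi = med / fold_window, med * fold_window
    keep = frame["syfp_mean"].between(lo, hi) & ~frame["excluded"]
    log = frame.loc[~keep, ["field_id", "cell_id", "syfp_mean", "excluded", "exclusion_reason"]].copy()
    log["lo"], log["hi"] = lo, hi
    return frame.loc[keep].copy(), log


def summarize_timepoints(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean +- s.e.m. of the ratio per (ligand, time_min) group.

    s.e.m. = sample standard deviation / sqrt(n); undefined (NaN) for
    single-cell groups.
    """
    if frame.empty:
        return pd.DataFrame(columns=["ligand", "time_min", "mean", "sem", "n"])
    rows = []
    for (ligand, t), g in frame.groupby(["ligand", "time_min"], sort=True):
        r = g["ratio"].dropna()
        if len(r) == 0:
            continue
        rows.append(
            {
                "ligand": ligand,
                "time_min": t,
                "mean": float(r.mean()),
                "sem": float(r.std(ddof=1) / math.sqrt(len(r))) if len(r) > 1 else np.nan,
                "n": int(len(r)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TestResult:
    """Two-sample t-test outcome (two-tailed)."""

    statistic: float
    df: float
    p_two_tailed: float
    method: str
    flags: list = field(default_factory=list)


def t_test_two_sample(a, b, method: str = "student_pooled") -> TestResult:
    """Two-tailed t-test on raw per-cell values.

    ``student_pooled`` is the classical equal-variance Student test;
    ``welch`` drops the equal-variance assumption.  Two identical
    zero-variance samples report p = 1 with a flag instead of NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    flags = []
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            flags.append("zero variance, equal means")
            df = len(a) + len(b) - 2 if method == "student_pooled" else float(len(a) + len(b) - 2)
            return TestResult(0.0, float(df), 1.0, method, flags)
    if method == "student_pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    else:
        raise ValueError(f"unknown t-test method: {method!r}")
    return TestResult(float(res.statistic), float(df), float(res.pvalue), method, flags)


def t_test_from_summary(mean1, sem1, n1, mean2, sem2, n2) -> TestResult:
    """Two-tailed t-test from published (mean, sem, n) summaries.

    t = (m1 - m2) / sqrt(sem1^2 + sem2^2), with Welch-Satterthwaite degrees
    of freedom computed from the sems and group sizes.  Used when only
    summary tables are available.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = sem1**2, sem2**2
    if v1 + v2 == 0:
        raise ValueError("both sems are zero: t undefined")
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "from_summary")
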