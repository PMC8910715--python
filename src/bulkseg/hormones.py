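"""Hormone quantification from calibration curves and group comparison.

Concentrations (ng/g) come from inverting per-compound OLS calibration
lines fitted to standards; class totals (IAA, GA, ABA, SL, CK, ETH, BR) are
sums over member compounds per replicate, compared between tall and dwarf
groups with Welch t-tests and the conventional significance stars
(* p < 0.05, ** p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "Quantification",
    "fit_calibration",
    "quantify",
    "welch_t_test",
    "stars",
    "class_totals",
    "fold_change_range",
    "compare_groups",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Straight-line response = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    compound: str = ""


@dataclass(frozen=True)
class Quantification:
    value: float
    below_loq: bool  # peak area fell below the calibration intercept


def fit_calibration(
    concentrations, responses, compound: str = "", weighted: bool = False
) -> CalibrationCurve:
    """OLS calibration line over >= 3 standards; optional 1/x weighting."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct standard concentrations")
    if weighted:
        w = 1.0 / np.where(x > 0, x, np.min(x[x > 0]))
        sw = w.sum()
        xb, yb = (w * x).sum() / sw, (w * y).sum() / sw
        slope = (w * (x - xb) * (y - yb)).sum() / (w * (x - xb) ** 2).sum()
        intercept = yb - slope * xb
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if sst == 0 else 1.0 - (resid**2).sum() / sst
    return CalibrationCurve(float(slope), float(intercept), float(r2), compound)


def quantify(curve: CalibrationCurve, peak_area: float, dilution: float = 1.0) -> Quantification:
    """Invert the calibration line; negative results floor at 0 with a flag."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (peak_area - curve.intercept) / curve.slope * dilution
    if conc < 0:
        return Quantification(0.0, True)
    return Quantification(float(conc), False)


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance t-test with Satterthwaite df; returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate replicates: equal constants are indistinguishable (p = 1),
        # unequal constants separate perfectly (p -> 0)
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), float(
            len(a) + len(b) - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def class_totals(panel: pd.DataFrame) -> pd.DataFrame:
    """Sum member-compound concentrations per class, group and replicate."""
    return (
        panel.groupby(["class", "group", "replicate"])["concentration"]
        .sum()
        .rename("total")
        .reset_index()
    )


def fold_change_range(tall_totals, dwarf_totals) -> tuple[float, float]:
    """(min, max) of per-replicate dwarf/tall ratios, paired by replicate index."""
    t = np.asarray(tall_totals, dtype=float)
    d = np.asarray(dwarf_totals, dtype=float)
    if len(t) != len(d):
        raise ValueError("replicate counts differ between groups")
    if np.any(t == 0):
        raise ValueError("zero tall-group total: fold change undefined")
    ratios = d / t
    return float(ratios.min()), float(ratios.max())


def compare_groups(panel: pd.DataFrame, by: str = "class") -> pd.DataFrame:
    """Per-class (or per-compound) tall-vs-dwarf comparison table.

    Columns: mean and SE per group, per-replicate fold-change range
    (dwarf/tall), Welch t, df, p and stars.
    """
    key = "class" if by == "class" else "compound"
    if by == "class":
        data = class_totals(panel)
        value = "total"
    else:
        data = panel.rename(columns={"concentration": "total"})
        value = "total"
    rows = []
    for name, sub in data.groupby(key, sort=False):
        tall = sub.loc[sub["group"] == "tall"].sort_values("replicate")[value].to_numpy()
        dwarf = sub.loc[sub["group"] == "dwarf"].sort_values("replicate")[value].to_numpy()
        t, df, p = welch_t_test(tall, dwarf)
        lo, hi = fold_change_range(tall, dwarf)
        rows.append(
            {
                key: name,
                "mean_tall": tall.mean(),
                "se_tall": tall.std(ddof=1) / np.sqrt(len(tall)),
                "mean_dwarf": dwarf.mean(),
                "se_dwarf": dwarf.std(ddof=1) / np.sqrt(len(dwarf)),
                "fold_min": lo,
                "fold_max": hi,
                "t": t,
                "df": df,
                "p": p,
                "stars": stars(p),
            }
        )
    return pd.DataFrame(rows)
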