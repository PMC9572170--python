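"""Patient-versus-control statistics over per-subject feature aggregates.

Each subject's 5-min interval features are reduced, separately for awake and
sleep intervals, to the mean and standard deviation of every feature type
(14 types -> 28 aggregate values). Group differences are assessed with
two-tailed Mann-Whitney U tests and Benjamini-Hochberg FDR adjustment across
the whole feature family of one state; medians and IQRs are tabulated for
each group. A separate balance check compares recorded-interval counts with
a Shapiro-Wilk-gated t-test (Mann-Whitney fallback under non-normality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import STAT_FEATURES

__all__ = [
    "aggregate_subject",
    "mann_whitney_u",
    "bh_adjust",
    "group_comparison",
    "recorded_balance_check",
    "boxplot_summary",
    "EXACT_MAX_N",
]

#: Largest combined sample size for which the exact U distribution is
#: enumerated (ties always fall back to the normal approximation).
EXACT_MAX_N = 12


def aggregate_subject(intervals: pd.DataFrame, subject_id: str, group: str,
                      features: list | None = None) -> pd.DataFrame:
    """Mean and sample SD of each feature type per state for one subject.

    ``intervals`` holds one row per 5-min window with a ``state`` column.
    States with fewer than 2 intervals are flagged (``flag`` column) since
    their SD is undefined. Returns one row per state with 2 x len(features)
    aggregate columns named ``<feature>_mean`` / ``<feature>_std``.
    """
    features = features if features is not None else STAT_FEATURES
    rows = []
    for state, sub in intervals.groupby("state"):
        row = {"subject_id": subject_id, "group": group, "state": state,
               "n_intervals": len(sub), "flag": len(sub) < 2}
        for feat in features:
            vals = sub[feat].dropna().to_numpy() if feat in sub else np.empty(0)
            row[f"{feat}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{feat}_std"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def mann_whitney_u(group_a, group_b) -> tuple:
    """Two-tailed Mann-Whitney U test (U of the first group, p-value).

    Uses exact enumeration when the combined sample is small (<= 12) and
    tie-free, and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def group_comparison(summaries: pd.DataFrame, state: str,
                     alpha: float = 0.05,
                     features: list | None = None) -> pd.DataFrame:
    """Per-feature group comparison table for one state.

    One row per aggregate feature with group medians and IQRs, the U
    statistic, raw and BH-adjusted p-values (adjusted across all features of
    this run), and the significance flag at ``alpha``.
    """
    features = features if features is not None else STAT_FEATURES
    sub = summaries[summaries["state"] == state]
    controls = sub[sub["group"] == "control"]
    patients = sub[sub["group"] == "patient"]
    if len(controls) < 2 or len(patients) < 2:
        raise ValueError("need at least 2 subjects per group")
    columns = [f"{f}_{stat}" for f in features for stat in ("mean", "std")]
    missing = [c for c in columns if c not in sub.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    rows = []
    for col in columns:
        c = controls[col].dropna().to_numpy()
        p_ = patients[col].dropna().to_numpy()
        u, pval = mann_whitney_u(c, p_)
        rows.append({
            "feature": col, "state": state,
            "control_median": float(np.median(c)), "control_iqr": _iqr(c),
            "patient_median": float(np.median(p_)), "patient_iqr": _iqr(p_),
            "U": u, "p_raw": pval,
        })
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table


@dataclass
class BalanceCheck:
    shapiro_p_a: float
    shapiro_p_b: float
    normal: bool
    test: str                   # "t" | "mannwhitney"
    p_value: float


def recorded_balance_check(counts_a, counts_b, alpha: float = 0.05) -> BalanceCheck:
    """Compare recorded-interval counts between groups.

    Welch's t-test when both groups pass Shapiro-Wilk normality at ``alpha``,
    otherwise a two-tailed Mann-Whitney U fallback.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return BalanceCheck(1.0, 1.0, True, "t", 1.0)
    pa = float(stats.shapiro(a).pvalue) if len(np.unique(a)) > 1 else 0.0
    pb = float(stats.shapiro(b).pvalue) if len(np.unique(b)) > 1 else 0.0
    normal = pa > alpha and pb > alpha
    if normal:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        return BalanceCheck(pa, pb, True, "t", p)
    _, p = mann_whitney_u(a, b)
    return BalanceCheck(pa, pb, False, "mannwhitney", p)


def boxplot_summary(values) -> dict:
    """Median, quartiles, 1.5*IQR whiskers and outliers (plot-ready JSON)."""
    x = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(inside.min()) if len(inside) else float(q1),
        "whisker_high": float(inside.max()) if len(inside) else float(q3),
        "outliers": [float(v) for v in x[(x < lo_fence) | (x > hi_fence)]],
    }
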