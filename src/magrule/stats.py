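"""Cohort statistics: Welch comparisons, correlation, category summaries.

The Welch statistic and the Pearson coefficient are implemented from their
textbook formulas (only the t-distribution CDF comes from scipy), so tests
can cross-check them against an independent library implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "CategorySummary",
    "welch_t_test",
    "pearson_r",
    "category_summary",
    "ish_subgroup_comparison",
]

ALPHA_DEFAULT = 0.01  # significance level used throughout

VALID_SCORE_LABELS = ("0", "1+", "2+", "3+")


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant_at_1pct: bool

    def as_dict(self) -> Dict[str, object]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    pearson_r: float
    subset: str = ""


def welch_t_test(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    alpha: float = ALPHA_DEFAULT,
) -> GroupComparison:
    """Two-sided Welch two-sample t-test (unequal variances).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va <= 0 and vb <= 0:
        if a.mean() == b.mean():
            # identical constant samples: no evidence of difference
            return GroupComparison(
                label_a, label_b, a.size, b.size, float(a.mean()), float(b.mean()),
                0.0, 0.0, 0.0, float(a.size + b.size - 2), 1.0, False,
            )
        raise ValueError("both samples have zero variance")
    sa = va / a.size
    sb = vb / b.size
    se = math.sqrt(sa + sb)
    t = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (
        (sa**2 / (a.size - 1)) + (sb**2 / (b.size - 1))
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return GroupComparison(
        label_a,
        label_b,
        int(a.size),
        int(b.size),
        float(a.mean()),
        float(b.mean()),
        float(math.sqrt(va)),
        float(math.sqrt(vb)),
        float(t),
        float(df),
        p,
        p < alpha,
    )


def pearson_r(
    x: Sequence[float], y: Sequence[float], subset: str = ""
) -> CorrelationResult:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx <= 0 or syy <= 0:
        raise ValueError("constant input has undefined correlation")
    r = float(np.sum(dx * dy) / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(int(x.size), r, subset)


@dataclass
class CategorySummary:
    """Per-category descriptive statistics plus pairwise Welch comparisons."""

    summary: pd.DataFrame
    cell_width_hist: pd.DataFrame
    specimen_width_hist: pd.DataFrame
    pairwise_width: List[GroupComparison]
    pairwise_intensity: List[GroupComparison]


def _check_scores(labels) -> None:
    bad = set(str(v) for v in labels) - set(VALID_SCORE_LABELS)
    if bad:
        raise ValueError(f"unknown score labels: {sorted(bad)}")


def _hist(values: np.ndarray, bin_width: float) -> pd.DataFrame:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return pd.DataFrame({"bin_left_um": [], "bin_right_um": [], "count": []})
    hi = math.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left_um": edges[:-1], "bin_right_um": edges[1:], "count": counts}
    )


def category_summary(
    cells: pd.DataFrame,
    specimens: pd.DataFrame,
    bin_width_um: float = 0.1,
    group_col: str = "score_preset",
) -> CategorySummary:
    """Per-score width/intensity summaries, histograms, pairwise Welch tests.

    ``group_col`` selects the grouping label (the generating preset for
    synthetic cohorts, or the assigned score for real-mode tables).
    """
    if cells.empty or specimens.empty:
        raise ValueError("cells and specimens tables must be non-empty")
    for frame in (cells, specimens):
        if group_col not in frame.columns:
            raise ValueError(f"missing grouping column {group_col!r}")
        _check_scores(frame[group_col].unique())

    rows = []
    for label, cgroup in cells.groupby(group_col, sort=True):
        sgroup = specimens[specimens[group_col] == label]
        widths = cgroup["mean_width_um"].to_numpy(float)
        intens = cgroup["mean_intensity_pct"].to_numpy(float)
        smeans = sgroup["mean_width_um"].to_numpy(float)
        rows.append(
            {
                "score": label,
                "n_cells": len(cgroup),
                "n_specimens": len(sgroup),
                "cell_width_mean_um": np.nanmean(widths),
                "cell_width_sd_um": np.nanstd(widths, ddof=1) if len(widths) > 1 else np.nan,
                "cell_intensity_mean_pct": np.nanmean(intens),
                "cell_intensity_sd_pct": np.nanstd(intens, ddof=1) if len(intens) > 1 else np.nan,
                "specimen_width_mean_um": np.nanmean(smeans) if len(smeans) else np.nan,
                "specimen_width_sd_um": np.nanstd(smeans, ddof=1) if len(smeans) > 1 else np.nan,
            }
        )
    summary = pd.DataFrame(rows)

    pairwise_w: List[GroupComparison] = []
    pairwise_i: List[GroupComparison] = []
    labels = sorted(specimens[group_col].unique())
    for la, lb in itertools.combinations(labels, 2):
        wa = specimens.loc[specimens[group_col] == la, "mean_width_um"].dropna()
        wb = specimens.loc[specimens[group_col] == lb, "mean_width_um"].dropna()
        if len(wa) >= 2 and len(wb) >= 2:
            pairwise_w.append(welch_t_test(wa, wb, str(la), str(lb)))
        ia = specimens.loc[specimens[group_col] == la, "mean_intensity_pct"].dropna()
        ib = specimens.loc[specimens[group_col] == lb, "mean_intensity_pct"].dropna()
        if len(ia) >= 2 and len(ib) >= 2:
            pairwise_i.append(welch_t_test(ia, ib, str(la), str(lb)))

    return CategorySummary(
        summary=summary,
        cell_width_hist=_hist(cells["mean_width_um"].to_numpy(float), bin_width_um),
        specimen_width_hist=_hist(
            specimens["mean_width_um"].to_numpy(float), bin_width_um
        ),
        pairwise_width=pairwise_w,
        pairwise_intensity=pairwise_i,
    )


def ish_subgroup_comparison(
    specimens: pd.DataFrame, group_col: str = "score_preset"
) -> Dict[str, GroupComparison]:
    """Welch comparisons of width and intensity between ISH label groups.

    Operates on the 2+ subset (the only category carrying ISH labels).
    """
    sub = specimens
    if group_col in sub.columns:
        sub = sub[sub[group_col].astype(str) == "2+"]
    pos = sub[sub["ish_label"] == "positive"]
    neg = sub[sub["ish_label"] == "negative"]
    if pos.empty or neg.empty:
        raise ValueError("both ISH label groups must be present")
    return {
        "width": welch_t_test(
            pos["mean_width_um"], neg["mean_width_um"], "ISH+", "ISH-"
        ),
        "intensity": welch_t_test(
            pos["mean_intensity_pct"], neg["mean_intensity_pct"], "ISH+", "ISH-"
        ),
    }


def comparisons_frame(comparisons: Sequence[GroupComparison], metric: str = "") -> pd.DataFrame:
    """Flatten GroupComparison records into a table for CSV export."""
    rows = []
    for c in comparisons:
        d = c.as_dict()
        if metric:
            d["metric"] = metric
        rows.append(d)
    return pd.DataFrame(rows)
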