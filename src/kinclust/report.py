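"""Summary artifacts: DfC mean/SD grids, frequency tables, per-feature tests.

Quantitative outputs are plain CSV-friendly DataFrames; bar-chart rendering is
an optional extra so no downstream consumer ever parses an image.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dfc import DfCResult, wilcoxon_ranksum
from .inventory import FEATURE_NAMES

logger = logging.getLogger(__name__)

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p_value: float) -> str:
    for level, mark in STAR_LEVELS:
        if p_value < level:
            return mark
    return ""


def frequency_summary(results: list[DfCResult], axis: str) -> pd.DataFrame:
    """Share of significant results carried by each task (or DOF).

    Restricted to results flagged significant; percentages are of the
    significant total and reported to one decimal, so each table's column sums
    to 100 up to rounding. An empty table (no significant results) is returned
    with a warning.
    """
    if axis not in ("task", "dof"):
        raise ValueError("axis must be 'task' or 'dof'")
    conditions = {r.condition for r in results}
    if len(conditions) > 1:
        raise ValueError(
            f"frequency_summary expects results from one condition, got {conditions}"
        )
    significant = [r for r in results if r.significant]
    if not significant:
        logger.warning("no significant results; frequency table is empty")
        return pd.DataFrame(columns=[axis, "count", "percent"])
    labels = pd.Series([getattr(r, axis) for r in significant])
    counts = labels.value_counts().sort_index()
    table = pd.DataFrame(
        {
            axis: counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(counts.to_numpy() / len(significant) * 100.0, 1),
        }
    ).reset_index(drop=True)
    return table


def dfc_bar_table(results: list[DfCResult]) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of the iteration DfC values per cell.

    The grid must be complete: every (condition, task, dof) combination of the
    conditions, tasks and DOFs present must appear exactly once.
    """
    if not results:
        raise ValueError("no results to summarize")
    keys = {(r.condition, r.task, r.dof) for r in results}
    conditions = sorted({k[0] for k in keys})
    tasks = sorted({k[1] for k in keys})
    dofs = sorted({k[2] for k in keys})
    missing = [
        (c, t, d)
        for c in conditions
        for t in tasks
        for d in dofs
        if (c, t, d) not in keys
    ]
    if missing:
        raise ValueError(f"incomplete results grid; missing cells: {missing[:10]}")
    rows = [
        {
            "condition": r.condition,
            "task": r.task,
            "dof": r.dof,
            "mean_dfc": r.mean_dfc,
            "sd_dfc": r.sd_dfc,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def plot_dfc_bars(
    bar_table: pd.DataFrame, out_path, threshold: float = 25.0
) -> None:
    """Optional bar-chart rendering of a dfc_bar_table, one panel per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conditions = sorted(bar_table["condition"].unique())
    fig, axes = plt.subplots(
        len(conditions), 1, figsize=(14, 4 * len(conditions)), squeeze=False
    )
    for ax, condition in zip(axes.ravel(), conditions):
        sub = bar_table[bar_table["condition"] == condition]
        labels = sub["task"] + "/" + sub["dof"]
        x = np.arange(len(sub))
        ax.bar(x, sub["mean_dfc"], yerr=sub["sd_dfc"], color="steelblue")
        for xi, (_, row) in zip(x, sub.iterrows()):
            if row["significant"]:
                ax.text(xi, row["mean_dfc"] + row["sd_dfc"] + 1, "*", ha="center")
        ax.axhline(threshold, color="red", linestyle=":")
        ax.set_ylabel(f"DfC ({condition})")
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=90, fontsize=4)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def feature_distribution_tests(
    features: pd.DataFrame, condition: str
) -> pd.DataFrame:
    """Two-sided rank-sum of each feature, bypass vs Norm, per (task, DOF).

    Cells where either group has fewer than 2 observations are marked NA.
    Star levels: * p<0.05, ** p<0.01, *** p<0.001.
    """
    rows = []
    grouped = features.groupby(["task", "dof"], sort=True)
    for (task, dof), cell in grouped:
        bypass = cell[cell["condition"] == condition]
        norm = cell[cell["condition"] == "Norm"]
        for feature in FEATURE_NAMES:
            a = bypass[feature].to_numpy(float)
            b = norm[feature].to_numpy(float)
            if a.size < 2 or b.size < 2:
                p = np.nan
            else:
                p = wilcoxon_ranksum(a, b, side="two-sided")
            rows.append(
                {
                    "condition": condition,
                    "task": task,
                    "dof": dof,
                    "feature": feature,
                    "p_value": p,
                    "stars": "" if np.isnan(p) else stars(p),
                }
            )
    return pd.DataFrame(rows)
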