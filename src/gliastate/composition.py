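"""Cellularity tables and between-group composition tests.

Cellularity is the per-animal percentage of cells of each type, either of
all retained cells in that animal or of a parent lineage (e.g. T-cell
subtypes as a percentage of all T-cells). Group differences are assessed
per cell type with a Welch two-sample t-test on the per-sample percentages,
and boxplot summaries follow the Tukey hinge/whisker convention (type-7
quartile hinges, whiskers at the most extreme data values within 1.5 IQR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import validate_annotation

__all__ = ["cellularity", "compare_groups", "boxplot_stats", "BoxplotStats", "star_bin"]


def cellularity(
    annot: pd.DataFrame,
    cell_type_col: str = "cell_type",
    parent: set | list | None = None,
    exclude_clusters: set | None = None,
    cluster_col: str = "cluster",
) -> pd.DataFrame:
    """Per-(sample, cell type) counts and percentages.

    ``pct_of_total`` is the percentage of all of the sample's cells;
    ``pct_of_parent`` (when ``parent`` gives the lineage's cell types) is
    the percentage of the sample's parent-lineage cells. Cells in
    ``exclude_clusters`` (e.g. flagged doublet clusters) are removed first.
    """
    annot = validate_annotation(annot)
    if cell_type_col not in annot.columns:
        raise ValueError(f"annotation lacks a {cell_type_col!r} column")
    if exclude_clusters:
        if cluster_col not in annot.columns:
            raise ValueError(f"annotation lacks a {cluster_col!r} column for exclusion")
        annot = annot[~annot[cluster_col].isin(exclude_clusters)]
    empty = annot.groupby("sample_id").size() == 0
    if annot.empty:
        warnings.warn("no cells left after exclusion; empty cellularity table")
        return pd.DataFrame(
            columns=["sample_id", "group", "cell_type", "n_cells", "pct_of_total", "pct_of_parent"]
        )

    counts = (
        annot.groupby(["sample_id", "group", cell_type_col], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
        .rename(columns={cell_type_col: "cell_type"})
    )
    totals = counts.groupby("sample_id")["n_cells"].transform("sum")
    counts["pct_of_total"] = 100.0 * counts["n_cells"] / totals

    if parent is not None:
        parent = set(parent)
        in_parent = counts["cell_type"].isin(parent)
        parent_totals = (
            counts[in_parent].groupby("sample_id")["n_cells"].sum().rename("parent_total")
        )
        counts = counts.merge(parent_totals, on="sample_id", how="left")
        counts["pct_of_parent"] = np.where(
            in_parent & (counts["parent_total"] > 0),
            100.0 * counts["n_cells"] / counts["parent_total"],
            np.nan,
        )
        counts = counts.drop(columns="parent_total")
    else:
        counts["pct_of_parent"] = np.nan
    return counts.sort_values(["sample_id", "cell_type"], kind="stable").reset_index(drop=True)


def star_bin(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001 (else 'ns')."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    cell_type: str,
    value_col: str = "pct_of_total",
) -> dict:
    """Welch two-sample t-test on per-sample percentages of one cell type.

    Returns the statistic, Welch–Satterthwaite degrees of freedom, the
    two-sided p-value and a star bin. Samples lacking the cell type
    contribute 0%. If both groups are constant and equal, p = 1 by
    convention; constant but unequal groups are reported as undefined.
    """
    sub = table[table["cell_type"] == cell_type]
    samples = table[["sample_id", "group"]].drop_duplicates().set_index("sample_id")["group"]

    def values_for(g: str) -> np.ndarray:
        ids = samples.index[samples == g]
        if len(ids) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples, found {len(ids)}")
        v = sub.set_index("sample_id")[value_col].reindex(ids)
        return v.fillna(0.0).to_numpy(dtype=float)

    a, b = values_for(group_a), values_for(group_b)
    base = {
        "cell_type": cell_type,
        "group_a": group_a,
        "group_b": group_b,
        "n_a": len(a),
        "n_b": len(b),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return {**base, "t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0, "stars": "ns"}
        return {**base, "t": np.nan, "df": np.nan, "p": np.nan, "stars": "undefined"}
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return {**base, "t": t, "df": df, "p": p, "stars": star_bin(p)}


@dataclass
class BoxplotStats:
    """Tukey box summary of one group of values."""

    lower_hinge: float
    upper_hinge: float
    whisker_low: float
    whisker_high: float
    median: float
    outliers: list


def boxplot_stats(values) -> BoxplotStats:
    """Hinges at type-7 quartiles; whiskers at the most extreme data values
    within 1.5 IQR of the hinges; anything beyond is an outlier."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("boxplot statistics need at least one value")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation = type 7
    iqr = q3 - q1
    lo_limit, hi_limit = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_limit) & (v <= hi_limit)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = sorted(float(x) for x in v[(v < lo_limit) | (v > hi_limit)])
    return BoxplotStats(
        lower_hinge=float(q1),
        upper_hinge=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        median=float(q2),
        outliers=outliers,
    )
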