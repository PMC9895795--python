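"""Differential-expression table screening.

This module consumes DE summary tables (gene, comparison, log2 fold change,
raw and/or adjusted p-value) produced upstream (e.g. by DESeq2) or by the
synthetic generator; it does not refit any count model. Screening uses the
strict criteria |log2FC| > lfc_min and padj < padj_max (defaults 0 and 0.05),
with Benjamini-Hochberg adjustment applied to raw p-values when no adjusted
column is present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEG_COLUMNS = ["gene", "comparison", "log2fc", "pvalue", "padj"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j>=i} p_(j) * m / j over the ascending order statistics,
    capped at 1; ties share a value. Monotone: p_a <= p_b implies
    adj_a <= adj_b.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_deg_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = {"gene", "comparison", "log2fc"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} is missing columns {sorted(missing)}")
    for col in ("pvalue", "padj"):
        if col not in df.columns:
            df[col] = np.nan
    return df[DEG_COLUMNS]


def write_deg_table(df: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)


def filter_degs(
    table: pd.DataFrame,
    lfc_min: float = 0.0,
    padj_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen DEGs with |log2fc| > lfc_min AND padj < padj_max (both strict).

    Rows without a padj get one via BH over their comparison's raw p-values.
    Returns (filtered table with a ``direction`` column, up/down counts per
    comparison).
    """
    df = table.copy()
    if "padj" not in df.columns:
        df["padj"] = np.nan
    # BH per comparison for rows lacking padj
    for comparison, block in df.groupby("comparison", sort=False):
        mask = block["padj"].isna()
        if mask.any():
            if block.loc[mask, "pvalue"].isna().any():
                raise ValueError(
                    f"comparison {comparison!r} has rows with neither pvalue nor padj"
                )
            adj = bh_adjust(block.loc[mask, "pvalue"].to_numpy())
            df.loc[block.index[mask], "padj"] = adj

    keep = (df["log2fc"].abs() > lfc_min) & (df["padj"] < padj_max)
    filtered = df[keep].copy()
    filtered["direction"] = np.where(filtered["log2fc"] > 0, "up", "down")

    counts = (
        filtered.groupby(["comparison", "direction"]).size().unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    return filtered.reset_index(drop=True), counts
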