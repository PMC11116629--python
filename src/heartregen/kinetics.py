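"""Regeneration kinetics: normalization to negative control and summaries.

Per-larva ventricular areas are normalised at each timepoint to the
negative-control mean (set to 100), after robust outlier removal (ROUT,
Q = 1%) within each group x timepoint cell — the Prism-style order of
operations (flag outliers first, then analyse).  Larvae lost between
timepoints remain as gaps; dropout is reported, never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import rout_outliers

logger = logging.getLogger(__name__)

__all__ = ["normalize_to_control", "track_larvae", "summarize_kinetics", "plot_kinetics"]


def normalize_to_control(
    areas: pd.DataFrame,
    control_group: str = "negative_control",
    rout_q: float | None = 0.01,
    value_col: str = "area_um2",
) -> pd.DataFrame:
    """Build the kinetics table from a per-larva area table.

    ``areas`` needs columns well, group, timepoint and ``value_col``.
    Adds ``outlier_flag`` (ROUT at ``rout_q`` within each group x timepoint,
    skipped for cells with n < 3 or when ``rout_q`` is None) and
    ``normalized_area`` = 100 x area / mean(non-outlier control areas at that
    timepoint).  The non-outlier control mean is therefore exactly 100.
    """
    required = {"well", "group", "timepoint", value_col}
    missing = required - set(areas.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    df = areas.copy()
    df["outlier_flag"] = False
    if rout_q is not None:
        for (_, _), idx in df.groupby(["group", "timepoint"]).groups.items():
            vals = df.loc[idx, value_col].to_numpy(dtype=float)
            if len(vals) < 3:
                continue
            res = rout_outliers(vals, q=rout_q)
            df.loc[idx, "outlier_flag"] = res.outlier_flag

    control = df[df["group"] == control_group]
    if control.empty:
        raise ValueError(f"no rows for control group {control_group!r}")
    df["normalized_area"] = np.nan
    for tp, sub in df.groupby("timepoint"):
        ctrl = sub[(sub["group"] == control_group) & ~sub["outlier_flag"]]
        if ctrl.empty:
            raise ValueError(f"timepoint {tp!r} has no (non-outlier) control larvae")
        mean = ctrl[value_col].mean()
        if mean <= 0:
            raise ValueError(f"timepoint {tp!r}: control mean area is not positive")
        df.loc[sub.index, "normalized_area"] = 100.0 * sub[value_col] / mean
    return df


def track_larvae(kinetics: pd.DataFrame, value_col: str = "normalized_area") -> pd.DataFrame:
    """Wide per-well trajectory table (wells x timepoints).

    Wells missing a timepoint keep NaN gaps; the dropout count per timepoint
    is logged.  The well -> group mapping is carried as an index level.
    """
    wide = kinetics.pivot_table(index=["group", "well"], columns="timepoint", values=value_col, aggfunc="first")
    n_wells = wide.shape[0]
    for tp in wide.columns:
        missing = int(wide[tp].isna().sum())
        if missing:
            logger.info("dropout: %d of %d wells missing at %s", missing, n_wells, tp)
    return wide


def summarize_kinetics(
    kinetics: pd.DataFrame,
    value_col: str = "normalized_area",
    exclude_outliers: bool = True,
) -> pd.DataFrame:
    """Group x timepoint mean, SEM and n of the normalised areas.

    SEM = sd / sqrt(n); reported as NaN for single-observation cells.
    """
    if kinetics.empty:
        raise ValueError("empty kinetics table")
    df = kinetics
    if exclude_outliers and "outlier_flag" in df.columns:
        df = df[~df["outlier_flag"]]
    out = (
        df.groupby(["group", "timepoint"])[value_col]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan, n="count")
        .reset_index()
    )
    return out


def plot_kinetics(summary: pd.DataFrame, path: str | None = None):
    """Regeneration-kinetics graph: mean +/- SEM per group across timepoints."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, sub in summary.groupby("group"):
        sub = sub.sort_values("timepoint")
        ax.errorbar(sub["timepoint"], sub["mean"], yerr=sub["sem"], marker="o", capsize=3, label=group)
    ax.set_ylabel("BFP+ ventricular area (% of negative control)")
    ax.set_xlabel("timepoint")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
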