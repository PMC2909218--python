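"""Log2 transformation and within-array replicate collapse.

Raw median signals are log2-transformed, replicated probes are averaged
within each array (mean of the log2 values, not log2 of the mean — all
downstream statistics live on the log2 scale), and per-channel probes ×
arrays matrices are assembled.  Agilent control features are excluded from
the expression matrix, with one exception: the named negative-control probe
is collapsed like any replicated probe and kept as a row so that it can be
normalized alongside the data and later serve as the background estimate.

Replicate spread is summarised per probe group (sample SD, n−1 denominator)
and per array (mean replicate SD) — the within-array error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_agilent import ExpressionMatrix, FeatureTable
from .synthetic import NEGATIVE_CONTROL

__all__ = ["log2_transform", "CollapsedArray", "collapse_replicates", "build_matrix"]


def log2_transform(v):
    """Base-2 logarithm of positive signal(s); non-positive input is fatal."""
    arr = np.asarray(v, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("log2_transform requires strictly positive finite values")
    out = np.log2(arr)
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


@dataclass
class CollapsedArray:
    """One array's collapsed log2 signal for one channel."""

    array_id: str
    channel: str
    values: pd.Series  # unique probe -> mean log2 signal (controls excluded,
    #                    negative-control probe included)
    replicate_report: pd.DataFrame  # probe, mean, sd, count for groups with >= 2 features
    average_replicate_sd: float
    control_mean: float | None  # collapsed negative-control value, if present


def collapse_replicates(
    table: FeatureTable,
    channel: str,
    control_probe: str = NEGATIVE_CONTROL,
) -> CollapsedArray:
    """Collapse one array/channel to unique probes.

    Features with nonzero control type are excluded unless they carry the
    negative-control probe name.  Each probe takes the arithmetic mean of
    the log2 signals of its features; groups with ≥ 2 features contribute to
    the replicate report.  Output is sorted by probe name, so record order
    in the input is irrelevant and collapsing is idempotent.
    """
    frame = table.frame
    keep = (frame["control_type"].to_numpy() == 0) | (
        frame["probe_name"].to_numpy() == control_probe
    )
    sub = frame.loc[keep]
    if len(sub) == 0:
        raise ValueError(f"array {table.array_id!r}: no experimental features")

    log2sig = pd.Series(
        log2_transform(sub[
            "g_median_signal" if channel == "Cy3" else "r_median_signal"
        ].to_numpy()),
        index=sub["probe_name"].to_numpy(),
    )
    grouped = log2sig.groupby(level=0, sort=True)
    stats = grouped.agg(["mean", "std", "count"])
    stats.index.name = "probe"

    values = stats["mean"].rename(table.array_id)
    rep = stats.loc[stats["count"] >= 2].rename(columns={"std": "sd"})
    avg_sd = float(rep["sd"].mean()) if len(rep) else float("nan")
    control = float(values[control_probe]) if control_probe in values.index else None
    return CollapsedArray(
        array_id=table.array_id,
        channel=channel,
        values=values,
        replicate_report=rep.reset_index(),
        average_replicate_sd=avg_sd,
        control_mean=control,
    )


def build_matrix(
    tables: Sequence[FeatureTable],
    channel: str,
    control_probe: str = NEGATIVE_CONTROL,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse a set of arrays into one ExpressionMatrix.

    All arrays must share the same probe catalogue (same array design).
    Returns the matrix and a per-array replicate summary (array_id,
    average_replicate_sd, n_replicate_groups).
    """
    if not tables:
        raise ValueError("no arrays to assemble")
    collapsed = [collapse_replicates(t, channel, control_probe) for t in tables]
    df = pd.concat([c.values for c in collapsed], axis=1)
    if df.isna().any().any():
        raise ValueError("arrays do not share a common probe catalogue")
    summary = pd.DataFrame(
        {
            "array_id": [c.array_id for c in collapsed],
            "average_replicate_sd": [c.average_replicate_sd for c in collapsed],
            "n_replicate_groups": [len(c.replicate_report) for c in collapsed],
        }
    )
    return ExpressionMatrix(df, channel=channel), summary
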