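"""Expressed/not-expressed calling and between-channel interference.

Calling compares each probe's log2 signal to the negative-control background
plus a sliding threshold: a probe is "on" iff ``signal > background + t``
(strict, so a probe sitting exactly at background is off at threshold 0).
Sweeping ``t`` yields a monotone non-increasing call curve; contrasting the
curve of a real sample with that of an off-target hybridisation bounds the
false-positive rate of any chosen cutoff.

Interference quantifies the empirical coupling between large experimental
(Cy5) signal changes and the supposedly constant reference (Cy3) channel:
per bin of the Cy5 stimulation index, the Pearson correlation and OLS slope
of the Cy3 differences on the Cy5 differences, plus the same statistics for
the top-N probes by Cy5 change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_agilent import ExpressionMatrix, FeatureTable
from .preprocess import log2_transform
from .synthetic import NEGATIVE_CONTROL

__all__ = [
    "BackgroundModel",
    "CallCurve",
    "fit_background",
    "call_expressed",
    "channel_interference",
]


@dataclass
class BackgroundModel:
    """Negative-control background: per-array statistic + pooled distribution."""

    per_array: pd.Series  # array_id -> background statistic (log2)
    pooled: np.ndarray  # all negative-control log2 signals, for plotting
    statistic: str = "mean"
    control_probe: str = NEGATIVE_CONTROL

    def __post_init__(self) -> None:
        if len(self.pooled) == 0:
            raise ValueError("empty background distribution")
        if not np.all(np.isfinite(self.per_array.to_numpy())):
            raise ValueError("non-finite background statistic")

    @property
    def pooled_statistic(self) -> float:
        return float(np.mean(self.pooled) if self.statistic == "mean"
                     else np.median(self.pooled))


def _stat(values: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(np.mean(values))
    if statistic == "median":
        return float(np.median(values))
    raise ValueError(f"unknown background statistic {statistic!r}")


def fit_background(
    source: FeatureTable | Iterable[FeatureTable] | ExpressionMatrix,
    control_probe: str = NEGATIVE_CONTROL,
    channel: str = "Cy5",
    statistic: str = "mean",
) -> BackgroundModel:
    """Estimate the background from negative-control features.

    From FeatureTables the raw control features are log2-transformed and
    summarised per array (≥ 2 control features required); from a (collapsed,
    possibly normalized) ExpressionMatrix the control probe's row is used
    directly.  Missing controls are fatal, naming the expected probe id.
    """
    if isinstance(source, ExpressionMatrix):
        if control_probe not in source.data.index:
            raise ValueError(
                f"negative-control probe {control_probe!r} not found in matrix"
            )
        row = source.data.loc[control_probe]
        return BackgroundModel(per_array=row.astype(float),
                               pooled=row.to_numpy(float),
                               statistic=statistic, control_probe=control_probe)

    tables = [source] if isinstance(source, FeatureTable) else list(source)
    per_array = {}
    pooled = []
    for t in tables:
        mask = t.frame["probe_name"].to_numpy() == control_probe
        if mask.sum() < 2:
            raise ValueError(
                f"array {t.array_id!r}: expected >= 2 features of negative-control "
                f"probe {control_probe!r}, found {int(mask.sum())}"
            )
        col = "g_median_signal" if channel == "Cy3" else "r_median_signal"
        vals = log2_transform(t.frame.loc[mask, col].to_numpy())
        per_array[t.array_id] = _stat(vals, statistic)
        pooled.append(vals)
    return BackgroundModel(
        per_array=pd.Series(per_array, dtype=float),
        pooled=np.concatenate(pooled),
        statistic=statistic,
        control_probe=control_probe,
    )


@dataclass
class CallCurve:
    """Fraction of probes called 'on' per threshold above background."""

    thresholds: np.ndarray
    fraction_on: np.ndarray
    n_probes: int
    background: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fraction_on) > 1e-12):
            raise ValueError("call curve must be non-increasing in threshold")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fraction_on": self.fraction_on}
        )


def call_expressed(
    column: pd.Series | np.ndarray,
    background: BackgroundModel | float,
    thresholds: Sequence[float],
    exclude_control: bool = True,
    array_id: str | None = None,
) -> CallCurve:
    """Sweep on/off thresholds for one array column of log2 signal.

    ``background`` may be a scalar log2 statistic or a BackgroundModel (the
    array's own statistic is looked up via ``array_id``, defaulting to the
    column's name, falling back to the pooled statistic).
    """
    thresholds = np.asarray(list(thresholds), float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")

    if isinstance(column, pd.Series):
        name = array_id if array_id is not None else column.name
        values = column
        if exclude_control and isinstance(background, BackgroundModel):
            values = values.drop(background.control_probe, errors="ignore")
        values = values.to_numpy(float)
    else:
        name = array_id
        values = np.asarray(column, float)

    if isinstance(background, BackgroundModel):
        if name is not None and name in background.per_array.index:
            bg = float(background.per_array[name])
        else:
            bg = background.pooled_statistic
    else:
        bg = float(background)

    frac = np.array([(values > bg + t).mean() for t in thresholds])
    return CallCurve(thresholds=thresholds, fraction_on=frac,
                     n_probes=len(values), background=bg)


def channel_interference(
    d5: pd.Series | np.ndarray,
    d3: pd.Series | np.ndarray,
    bins: Sequence[tuple[float, float]] = ((2.5, 3.0), (3.0, 4.0), (4.0, np.inf)),
    top_n: int = 50,
) -> pd.DataFrame:
    """Coupling of matched per-probe Cy3 and Cy5 stimulation indices.

    ``bins`` are half-open intervals (lo, hi] on the Cy5 difference.  Rows
    with fewer than 3 probes report NaN statistics.  An extra row labelled
    ``top{N}`` covers the ``top_n`` probes with the largest Cy5 difference.
    """
    d5 = pd.Series(d5).astype(float)
    d3 = pd.Series(d3).astype(float)
    if len(d5) != len(d3):
        raise ValueError("d5 and d3 must be matched per probe")
    if isinstance(d5.index, pd.Index) and not d5.index.equals(d3.index):
        raise ValueError("d5 and d3 must share the same probe index")
    ivals = sorted(bins)
    for (lo1, hi1), (lo2, _) in zip(ivals, ivals[1:]):
        if lo2 < hi1:
            raise ValueError("bins must be disjoint")

    rows = []
    for lo, hi in bins:
        mask = (d5 > lo) & (d5 <= hi)
        rows.append(_bin_stats(f"({lo}, {hi}]", d5[mask], d3[mask]))
    order = np.argsort(-d5.to_numpy())[: int(top_n)]
    rows.append(_bin_stats(f"top{int(top_n)}", d5.iloc[order], d3.iloc[order]))
    return pd.DataFrame(rows)


def _bin_stats(label: str, d5: pd.Series, d3: pd.Series) -> dict:
    n = len(d5)
    if n < 3 or np.ptp(d5.to_numpy()) == 0:
        return {"bin": label, "count": n, "correlation": np.nan, "slope": np.nan}
    corr = float(stats.pearsonr(d5, d3).statistic)
    slope = float(stats.linregress(d5, d3).slope)
    return {"bin": label, "count": n, "correlation": corr, "slope": slope}
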