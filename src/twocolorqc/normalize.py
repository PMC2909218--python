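"""Between-array normalization against the mean reference.

Each array column ``y`` is regressed on the per-probe mean ``x`` of all
arrays, and the fitted systematic deviation from the identity line is
subtracted::

    y_corrected = y - (f(x) - x)

with ``f`` either a global ordinary-least-squares line (``linear``) or a
locally-weighted linear smooth (``loess``) whose neighbourhood fraction is
``1/segments`` — the classic "divide the signal range into 10 local data
sets" smoothing scale, realized as an overlapping-window smoother so the
correction is continuous in ``x``.  The reference ``x`` is computed once
from the input matrix and held fixed while every array is corrected (a
leave-one-out reference is available by flag).

Quantile normalization (the RMA preprocessing step) is provided for
comparison: every array's sorted values are replaced by the across-array
mean at each rank, ties receiving the average of the template at their
fractional rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_agilent import ExpressionMatrix

__all__ = [
    "LinearModel",
    "LoessModel",
    "QuantileTemplate",
    "mean_reference",
    "fit_linear",
    "apply_linear",
    "fit_loess",
    "apply_loess",
    "quantile_normalize",
    "normalize_matrix",
]


@dataclass(frozen=True)
class LinearModel:
    """Global OLS correction y ~ alpha + beta * x for one array."""

    array_id: str
    alpha: float
    beta: float
    method: str = "linear"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.alpha + self.beta * np.asarray(x, float)


@dataclass(frozen=True)
class LoessModel:
    """Locally-linear correction for one array, stored as (x, fitted) pairs.

    Evaluation interpolates linearly between fitted points and clamps at the
    ends, so the correction is defined for every x in the observed range.
    """

    array_id: str
    grid_x: np.ndarray
    grid_fitted: np.ndarray
    segments: int = 10
    method: str = "loess"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, float), self.grid_x, self.grid_fitted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.grid_x, "fitted": self.grid_fitted})


@dataclass(frozen=True)
class QuantileTemplate:
    """Across-array mean of sorted values, one entry per rank."""

    template: np.ndarray
    method: str = "quantile"


def mean_reference(m: ExpressionMatrix) -> pd.Series:
    """Per-probe arithmetic mean across arrays (the reference x)."""
    if m.n_arrays < 2:
        raise ValueError("mean reference requires at least 2 arrays")
    return m.data.mean(axis=1)


def fit_linear(y: np.ndarray, x: np.ndarray, array_id: str = "") -> LinearModel:
    """Ordinary least squares of y on x."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    if len(x) < 3:
        raise ValueError("linear fit requires at least 3 probes")
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("reference x has zero variance")
    res = stats.linregress(x, y)
    return LinearModel(array_id=array_id, alpha=float(res.intercept), beta=float(res.slope))


def apply_linear(y: np.ndarray, x: np.ndarray, model: LinearModel) -> np.ndarray:
    """Subtract the fitted deviation from identity: y − ((α + βx) − x)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    return y - (model.predict(x) - x)


def fit_loess(
    y: np.ndarray,
    x: np.ndarray,
    segments: int = 10,
    array_id: str = "",
) -> LoessModel:
    """Locally-weighted linear smooth of y on x at scale 1/segments.

    Requires at least ``10 * segments`` probes so every neighbourhood has a
    sensible population.  If one of the ``segments`` equal-width slices of
    the x range is empty the smoother's overlapping windows still cover it;
    a warning is emitted.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    if len(x) < 10 * segments:
        raise ValueError(f"loess fit requires at least {10 * segments} probes")
    if np.ptp(x) == 0:
        raise ValueError("reference x has zero range")

    edges = np.linspace(x.min(), x.max(), segments + 1)
    counts, _ = np.histogram(x, bins=edges)
    if (counts == 0).any():
        warnings.warn(
            f"array {array_id!r}: {(counts == 0).sum()} empty segment(s) in the x range; "
            "the overlapping loess neighbourhood covers them",
            stacklevel=2,
        )

    delta = 0.005 * float(np.ptp(x))
    fitted = _sm_lowess(y, x, frac=1.0 / segments, it=0, delta=delta, return_sorted=True)
    grid = pd.DataFrame(fitted, columns=["x", "f"]).groupby("x", sort=True)["f"].mean()
    return LoessModel(
        array_id=array_id,
        grid_x=grid.index.to_numpy(),
        grid_fitted=grid.to_numpy(),
        segments=segments,
    )


def apply_loess(y: np.ndarray, x: np.ndarray, model: LoessModel) -> np.ndarray:
    """Subtract the smoothed deviation from identity: y − (f(x) − x)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    return y - (model.predict(x) - x)


def quantile_normalize(m: ExpressionMatrix) -> tuple[ExpressionMatrix, QuantileTemplate]:
    """Force every array onto the across-array mean rank template.

    Ties within an array receive the template interpolated at their average
    rank, so tied inputs stay tied.
    """
    if m.n_arrays < 2:
        raise ValueError("quantile normalization requires at least 2 arrays")
    vals = m.values
    template = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    pos = np.arange(1, vals.shape[0] + 1, dtype=float)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, pos, template)
    return (
        ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                         channel=m.channel),
        QuantileTemplate(template=template),
    )


def normalize_matrix(
    m: ExpressionMatrix,
    method: str = "loess",
    segments: int = 10,
    leave_one_out: bool = False,
):
    """Normalize every array of a matrix against the mean reference.

    Returns ``(normalized_matrix, models)`` where ``models`` maps array id
    to the fitted per-array model (or holds the single
    :class:`QuantileTemplate` under the key ``"template"``).
    """
    if method == "quantile":
        norm, template = quantile_normalize(m)
        return norm, {"template": template}
    if method not in ("linear", "loess"):
        raise ValueError(f"unknown normalization method {method!r}")

    ref = mean_reference(m).to_numpy()
    n = m.n_arrays
    out = {}
    models = {}
    for j, array_id in enumerate(m.array_ids):
        y = m.data.iloc[:, j].to_numpy()
        if leave_one_out:
            x = (ref * n - y) / (n - 1)
        else:
            x = ref
        if method == "linear":
            model = fit_linear(y, x, array_id=array_id)
            out[array_id] = apply_linear(y, x, model)
        else:
            model = fit_loess(y, x, segments=segments, array_id=array_id)
            out[array_id] = apply_loess(y, x, model)
        models[array_id] = model
    norm = ExpressionMatrix(pd.DataFrame(out, index=m.data.index), channel=m.channel)
    return norm, models


def models_to_frame(models: dict) -> pd.DataFrame:
    """Flatten fitted models to a TSV-able table for inspection."""
    rows = []
    for key, model in models.items():
        if isinstance(model, LinearModel):
            rows.append({"array_id": model.array_id, "method": "linear",
                         "alpha": model.alpha, "beta": model.beta})
        elif isinstance(model, LoessModel):
            for xx, ff in zip(model.grid_x, model.grid_fitted):
                rows.append({"array_id": model.array_id, "method": "loess",
                             "x": xx, "fitted": ff})
        elif isinstance(model, QuantileTemplate):
            for i, t in enumerate(model.template):
                rows.append({"array_id": "*", "method": "quantile", "rank": i + 1,
                             "template": t})
    return pd.DataFrame(rows)
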