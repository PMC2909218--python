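"""The handful of diagnostic plots the pipeline produces.

matplotlib is imported lazily so that library use never pays for a plotting
backend.  All randomness (strip-plot jitter) comes from an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression_call import BackgroundModel, CallCurve
from .mds import MDSResult

__all__ = ["plot_pk_curve", "plot_mds_strips", "plot_background_hist", "plot_call_curves"]


def _agg():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_pk_curve(result: MDSResult, path: str) -> None:
    """Eigenvalues and the P_k goodness-of-fit curve, side by side."""
    plt = _agg()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    k = min(20, len(result.eigenvalues))
    ax1.plot(np.arange(1, k + 1), result.eigenvalues[:k], "o-")
    ax1.set_xlabel("dimension")
    ax1.set_ylabel("eigenvalue")
    kk = min(20, len(result.p_k))
    ax2.plot(np.arange(1, kk + 1), result.p_k[:kk], "o-")
    ax2.axhline(result.cutoff, ls="--", color="grey")
    ax2.set_xlabel("dimensions k")
    ax2.set_ylabel("$P_k$")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_mds_strips(
    result: MDSResult,
    path: str,
    color_by: str | None = None,
    n_dims: int = 10,
    jitter_seed: int = 0,
) -> None:
    """Per-dimension strip plots of MDS scores.

    Each dimension gets a vertical strip; a small seeded uniform x jitter
    separates overlapping arrays.  ``color_by`` names an annotation column.
    """
    plt = _agg()
    rng = np.random.default_rng(jitter_seed)
    coords = result.coordinates
    n_dims = min(n_dims, coords.shape[1])
    labels = None
    if color_by and result.annotations is not None and color_by in result.annotations:
        labels = result.annotations[color_by].reindex(coords.index).astype(str)
    fig, ax = plt.subplots(figsize=(1.1 * n_dims + 1, 4))
    if labels is not None:
        uniq = sorted(labels.unique())
        cmap = dict(zip(uniq, plt.rcParams["axes.prop_cycle"].by_key()["color"]))
    for j in range(n_dims):
        x = j + 1 + rng.uniform(-0.25, 0.25, size=len(coords))
        y = coords.iloc[:, j]
        if labels is not None:
            for lab in uniq:
                mask = (labels == lab).to_numpy()
                ax.scatter(x[mask], y[mask], s=12, color=cmap[lab],
                           label=lab if j == 0 else None)
        else:
            ax.scatter(x, y, s=12, color="black")
    if labels is not None:
        ax.legend(fontsize=8)
    ax.set_xticks(range(1, n_dims + 1))
    ax.set_xlabel("dimension")
    ax.set_ylabel("MDS score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_background_hist(bg: BackgroundModel, path: str, bins: int = 40) -> None:
    """Frequency distribution of the pooled negative-control log2 signal."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(bg.pooled, bins=bins, color="steelblue")
    ax.set_xlabel("log2 signal")
    ax.set_ylabel("features")
    ax.set_title("negative-control background")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_call_curves(curves: dict[str, CallCurve], path: str) -> None:
    """% of probes on vs threshold above background, one line per sample set."""
    plt = _agg()
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.plot(curve.thresholds, 100 * curve.fraction_on, "o-", label=label)
    ax.set_xlabel("threshold above background (log2 units)")
    ax.set_ylabel("% probes on")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
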