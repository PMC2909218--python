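"""Variance and error statistics for replicate array sets.

Covers the pipeline's quality metrics: the dependence of per-probe SD on
mean signal (OLS slope and R² of SD on mean), a per-probe Shapiro-Wilk
normality screen, genewise per-channel SD / between-channel covariance and
correlation, and the covariance-corrected SD of the between-channel
difference

    SD(E − R) = sqrt(SD_E² + SD_R² − 2·Cov(E, R)),

which quantifies how much (or little) working with Cy5/Cy3 log-ratios
buys over single-channel normalized signal.  All SDs and covariances use
the sample (n−1) convention, so the identity above is exact, not
asymptotic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_agilent import ExpressionMatrix

__all__ = [
    "SdVsMeanFit",
    "NormalityScreen",
    "VarianceReport",
    "sd_vs_mean",
    "normality_screen",
    "channel_stats",
    "sd_of_difference",
]


@dataclass(frozen=True)
class SdVsMeanFit:
    slope: float
    intercept: float
    r_squared: float
    stderr: float


def sd_vs_mean(m: ExpressionMatrix) -> SdVsMeanFit:
    """OLS of per-probe SD on per-probe mean across arrays."""
    if m.n_arrays < 3:
        raise ValueError("sd_vs_mean requires at least 3 arrays")
    means = m.data.mean(axis=1).to_numpy()
    sds = m.data.std(axis=1, ddof=1).to_numpy()
    res = stats.linregress(means, sds)
    return SdVsMeanFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
    )


@dataclass
class NormalityScreen:
    fraction_passing: float  # share of probes with raw Shapiro-Wilk p > alpha
    fraction_passing_bh: float  # same with Benjamini-Hochberg adjusted p
    alpha: float
    pvalues: pd.Series


def normality_screen(m: ExpressionMatrix, alpha: float = 0.05) -> NormalityScreen:
    """Per-probe Shapiro-Wilk test across arrays.

    Reports the raw fraction of probes whose distribution is not
    significantly non-normal (p > alpha) — deliberately uncorrected, as a
    descriptive screen — together with a Benjamini-Hochberg adjusted
    fraction for reference.
    """
    if m.n_arrays < 3:
        raise ValueError("normality screen requires at least 3 arrays")
    vals = m.values
    pvals = np.empty(vals.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n > 5000 / ties
        for i in range(vals.shape[0]):
            row = vals[i]
            if np.ptp(row) == 0:
                pvals[i] = 0.0  # degenerate constant probe: not testably normal
            else:
                pvals[i] = stats.shapiro(row).pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    return NormalityScreen(
        fraction_passing=float(np.mean(pvals > alpha)),
        fraction_passing_bh=float(np.mean(adj > alpha)),
        alpha=alpha,
        pvalues=pd.Series(pvals, index=m.data.index, name="shapiro_p"),
    )


def sd_of_difference(sd_e: float, sd_r: float, cov: float) -> float:
    """SD of the difference of two channels from their SDs and covariance.

    ``sqrt(sd_e² + sd_r² − 2·cov)``.  A tiny negative radicand (rounding)
    is clamped to zero with a warning; a substantive one is fatal.
    """
    if cov * cov > sd_e * sd_e * sd_r * sd_r * (1 + 1e-9) + 1e-12:
        raise ValueError("covariance inconsistent with the channel SDs")
    rad = sd_e * sd_e + sd_r * sd_r - 2.0 * cov
    if rad < 0:
        if rad < -1e-9:
            raise ValueError(f"negative variance of difference: {rad}")
        warnings.warn("radicand slightly negative; clamped to 0", stacklevel=2)
        rad = 0.0
    return math.sqrt(rad)


@dataclass
class VarianceReport:
    """Per-probe and summary variability of a matched Cy5/Cy3 array set.

    ``per_probe`` columns: mean/sd per channel, cov, corr, sd_diff (the
    directly computed SD of the per-probe Cy5−Cy3 difference).  ``summary``
    holds unweighted probe averages, the 95th-percentile genewise SDs, and
    the SD-of-difference formula evaluated on the averaged summaries (the
    headline-table convention).  Note that the average of per-probe
    correlations is reported as such; it is *not* the ratio of the averaged
    covariance to the product of averaged SDs.
    """

    per_probe: pd.DataFrame
    summary: pd.Series

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            for k, v in self.summary.items():
                fh.write(f"# summary\t{k}\t{v:.17g}\n")
            self.per_probe.to_csv(fh, sep="\t", index_label="probe_id",
                                  float_format="%.17g", lineterminator="\n")


def _summary_sd_of_difference(sd_e: float, sd_r: float, cov: float) -> float:
    """The difference formula on probe-*averaged* summaries (the headline-
    table convention).  Averaging SDs and covariances separately can be
    mutually inconsistent (Jensen), e.g. for perfectly correlated channels;
    then NaN is reported rather than a fabricated value."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sd_of_difference(sd_e, sd_r, cov)
    except ValueError:
        return float("nan")


def channel_stats(m5: ExpressionMatrix, m3: ExpressionMatrix) -> VarianceReport:
    """Genewise across-array statistics for matched Cy5/Cy3 matrices."""
    if list(m5.data.index) != list(m3.data.index):
        raise ValueError("Cy5 and Cy3 matrices must share the same probes, in order")
    if list(m5.data.columns) != list(m3.data.columns):
        raise ValueError("Cy5 and Cy3 matrices must share the same arrays, in order")
    n = m5.n_arrays
    if n < 2:
        raise ValueError("channel statistics require at least 2 arrays")

    v5 = m5.values
    v3 = m3.values
    mean5 = v5.mean(axis=1)
    mean3 = v3.mean(axis=1)
    c5 = v5 - mean5[:, None]
    c3 = v3 - mean3[:, None]
    var5 = (c5 * c5).sum(axis=1) / (n - 1)
    var3 = (c3 * c3).sum(axis=1) / (n - 1)
    cov = (c5 * c3).sum(axis=1) / (n - 1)
    sd5 = np.sqrt(var5)
    sd3 = np.sqrt(var3)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sd5 * sd3 > 0, cov / (sd5 * sd3), np.nan)
    diff = v5 - v3
    sd_diff = diff.std(axis=1, ddof=1)

    per_probe = pd.DataFrame(
        {
            "mean_cy5": mean5,
            "sd_cy5": sd5,
            "mean_cy3": mean3,
            "sd_cy3": sd3,
            "cov": cov,
            "corr": corr,
            "sd_diff": sd_diff,
        },
        index=m5.data.index,
    )
    summary = pd.Series(
        {
            "n_arrays": float(n),
            "n_probes": float(len(per_probe)),
            "sd_cy5_mean": float(sd5.mean()),
            "sd_cy3_mean": float(sd3.mean()),
            "cov_mean": float(cov.mean()),
            "corr_mean": float(np.nanmean(corr)),
            "sd_diff_mean": float(sd_diff.mean()),
            "sd_diff_eq": _summary_sd_of_difference(
                float(sd5.mean()), float(sd3.mean()), float(cov.mean())
            ),
            "sd_cy5_p95": float(np.percentile(sd5, 95)),
            "sd_cy3_p95": float(np.percentile(sd3, 95)),
        }
    )
    return VarianceReport(per_probe=per_probe, summary=summary)
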