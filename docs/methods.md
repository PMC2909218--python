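# Methods

## Scope and data model

The package operates on two-colour Agilent expression arrays: each scanned
array yields one Feature Extraction (FE) text file with a green (Cy3,
reference) and red (Cy5, experimental) median signal per spotted feature.
The working container is a probes × arrays matrix of log2 signal per
channel.  Only median signals are consumed; background-subtracted columns
and Agilent's feature flags are deliberately ignored — the pipeline's own
background estimate comes from the negative-control probe, and flag-based
filtering is out of scope.

Features whose signals are missing, non-numeric or ≤ 0 are dropped and
counted, never clamped: a clamped zero would poison the log2 transform and
bias the background distribution downward.

## Preprocessing

All statistics are computed on log2 signal.  The transform serves two
purposes, both verified by the test suite on synthetic data: it decouples
the per-probe SD from the mean signal (multiplicative scanner noise becomes
additive), and it brings per-probe distributions much closer to normality.

Replicated probes (263 probes spotted 10×, plus the negative control
spotted 153× on the emulated design) are collapsed within each array by the
arithmetic mean of their log2 values.  Mean-of-logs rather than
log-of-means keeps every downstream statistic on one scale; the per-group
sample SD (n−1 denominator, as everywhere in the package) is reported as
the intra-array error estimate.  Control features other than the named
negative-control probe are excluded from expression matrices.

## Normalization

Each array column `y` is corrected against the reference `x`, the per-probe
mean over all arrays (computed once and held fixed; the array under
correction is included in the mean by default, with a leave-one-out option).
The correction subtracts the fitted systematic deviation from the identity
line:

    ŷ = y − (f(x) − x)

* **linear** — `f` is the OLS line `α + βx`.
* **loess** — `f` is a locally weighted linear smooth whose neighbourhood
  fraction is `1/segments` (default 10).  The "10 equal segments" of the
  signal range fix the smoothing scale, but the smoother uses overlapping
  neighbourhoods rather than ten disjoint fits: disjoint fits would create
  step discontinuities in the correction.  The fit uses zero robustness
  iterations (plain weighted least squares) — the Gaussian-noise setting
  does not need robust reweighting and it keeps the smooth strictly
  deterministic and cheap — and is evaluated by linear interpolation
  between fitted points, clamped at the range ends, so the correction is
  defined and continuous over the whole observed range.  An empty segment
  of the x range triggers a warning, not an error; the overlapping
  neighbourhood covers it.
* **quantile** — every column's sorted values are replaced by the
  across-array mean at each rank; ties receive the template interpolated at
  their average rank, so tied inputs stay tied and the operation is
  deterministic.  Columns of unequal length are refused.

All three are near-idempotent on noiseless data (second application changes
values by < 1e-6), which the suite asserts.

## Variance statistics

For matched Cy5/Cy3 matrices the per-probe across-array mean, SD,
covariance and correlation are computed with sample (n−1) conventions
throughout, which makes the SD of the channel difference an exact identity
rather than an approximation:

    SD(E − R) = sqrt(SD_E² + SD_R² − 2·Cov(E, R))

Summary rows report unweighted probe averages.  Two caveats are built into
the report rather than papered over:

* the formula evaluated on *averaged* summaries (the headline-table
  convention) is not the average of per-probe SD(E−R); both are reported,
  and when the averaged inputs are mutually inconsistent (possible by
  Jensen's inequality, e.g. perfectly correlated channels) the summary
  value is NaN;
* the average of per-probe correlations is not the ratio of averaged
  covariance to averaged SDs; the report exposes per-probe correlations and
  their mean and makes no claim that the two conventions agree.

The Shapiro-Wilk screen reports the raw fraction of probes with p > 0.05 —
a descriptive calibration statistic, deliberately uncorrected for multiple
testing — alongside a Benjamini-Hochberg-adjusted fraction for reference.

## Expressed-gene calling

The background is the mean (configurable to median) of the
negative-control log2 signals, per array; the pooled control distribution
is retained for plotting.  A probe is called "on" iff signal >
background + threshold, with strict inequality so that a probe exactly at
background is off at threshold 0.  Call curves are monotone non-increasing
by construction and are validated against a brute-force count.

Channel interference — the empirical coupling of large Cy5 changes into
the reference channel — is quantified per bin of the Cy5 stimulation index
(default bins (2.5,3], (3,4], (4,∞] log2 units) as the Pearson correlation
and OLS slope of the matched Cy3 differences, plus the same statistics for
the top-50 probes by Cy5 change.  Bins with fewer than 3 probes report NaN.

## Classical MDS and dimension choice

Arrays are embedded from their pairwise Euclidean distance matrix by
Torgerson scaling (double-center −½·J·D²·J, eigendecompose, scale
eigenvectors by √λ).  For Euclidean distances this is equivalent to PCA of
the centered matrix, which the suite verifies to 1e-8.  Conventions:

* double-centering forces one zero eigenvalue, and numerical error can
  produce tiny negative ones; negative eigenvalues are clamped to zero in
  the goodness-of-fit statistic and excluded from coordinates, so
  `P_k = Σ_{i≤k} λ_i⁺ / Σ_i λ_i⁺` runs over the n−1 informative terms and
  reaches exactly 1 at k = n−1;
* the selected dimensionality is the smallest k with P_k ≥ 0.8 (cutoff
  configurable); if unreachable, n−1 is returned with a warning;
* eigenvector sign is arbitrary, so each axis is oriented to make its
  largest-magnitude loading positive — outputs are deterministic;
* strip plots jitter the x position from a seeded generator only.

## The synthetic generator

The generator emulates the study design end to end so that every pipeline
claim can be tested against known truth.  Per probe p, array a, channel c,
on the log2 scale:

    value = m_pc + o_a + (s_a − 1)(m_pc − μ) + k_a (m_pc − μ)² + ε

with array biases (offset o, slope s, curvature k) drawn uniformly from
±0.5, 0.9–1.1 and ±0.01 about the design centre μ = 8.5, and ε bivariate
Gaussian across channels.  Values are exponentiated into FE files (signals
span roughly 60–200,000 raw units).  Defaults are desk scale (2,000 unique
probes; `SimConfig.full_scale()` gives the 41,001-probe design) with 263
probes replicated 10× and the negative control spotted 153×.

Key modelling choices, stated as assumptions:

* **Gaussian noise on the log2 scale.**  Consistent with the observation
  that log2 array data approximate per-probe normality; not a claim about
  any particular real data set.
* **Expressed vs non-expressed probes.**  65% of probes are expressed by
  default, with true means drawn from N(8.5, 2.0) truncated one log2 unit
  above the background (log2(60) ≈ 5.91).  A non-transcribed probe's signal
  is pure background hybridisation: its true mean sits at the background
  level and only noise and array bias move it.
* **Technical/biological decomposition of the Cy5 noise.**  The configured
  Cy5 inter-array SD (0.52) is the *total* for an expressed probe.  Its
  technical component is shared with the reference channel — it is what
  carries the configured channel covariance (0.09), and is therefore at
  least `cov/SD_Cy3` — and affects every probe; the biological
  sample-to-sample remainder (quadrature complement) affects expressed
  probes only, since a probe with no transcript has nothing biological to
  vary.  Without this split, non-expressed probes would scatter with the
  full 0.52 SD and leak heavily past any calling threshold, which neither
  matches how real arrays behave nor leaves the planted expressed fraction
  recoverable.
* **Within-array replicate noise** of SD 0.16 (Cy3) / 0.20 (Cy5) with
  channel covariance 0.02 — replicate features of one probe share local
  print/hybridisation conditions, so their channel errors correlate.
* **Off-target sample.**  Emulates hybridising evolutionarily distant RNA:
  all probes draw from the background distribution except a small elevated
  fraction (default 2% at +1.5 log2 units) representing weak residual
  cross-hybridisation.

What the generator does **not** emulate — and hence what passing tests do
not show about real arrays: spatial surface artefacts, dye-swap designs,
probe-sequence-dependent affinity, saturation at the scanner ceiling,
batch-correlated biases, and non-Gaussian heavy-tailed outliers.  Tests
demonstrate that the pipeline recovers known truth under its stated model,
not that real arrays obey that model.

Determinism: one `numpy.random.Generator` seeded from `SimConfig.seed`
drives everything; identical configs produce byte-identical FE files
(signals are written with 17 significant digits, so noiseless files
reproduce the truth table to better than 1e-9 log2 units).

## Problem sizes and numerical conventions

Tests and examples run at desk scale — typically 300–2,000 probes and 4–20
arrays, with 5,000 probes × 77 arrays for the normality-screen calibration —
sizes at which every statistic of interest is estimated with comfortable
sampling error while the full suite stays fast.  Matrix TSVs are UTF-8,
tab-separated, '.' decimal, `%.17g` floats, read back with round-trip float
parsing, so write∘read is bit-exact.  Thresholds in call curves are
strict; SDs are sample SDs; OLS fits come from `scipy.stats.linregress`;
the LOESS smoother is `statsmodels`' lowess.

## Known limitations

* The LOESS weight kernel and neighbourhood definition follow the lowess
  tradition (tricube, nearest-neighbour fraction); a range-based window
  would be equally defensible.  The choice is validated by its contract —
  bias removal and continuity — not by equivalence to any particular other
  implementation.
* The summary-level SD-of-ratio convention (formula over probe-averaged
  inputs) is reported because it is the headline-table convention, but the
  per-probe average `sd_diff_mean` is the better-behaved statistic.
* Calling uses a single threshold family above a mean background; no
  attempt is made to model probe-specific background or to shrink
  per-probe variances.
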