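# twocolorqc

Processing, normalization, quality control and visualisation of Agilent
two-colour (Cy3/Cy5) oligonucleotide expression-array data — the kind of
study where every array carries one experimental sample (Cy5) against a
common reference RNA (Cy3), and the question is how much of the observed
variation is experimental error rather than biology.

The package is aimed at analysts working with Agilent Feature Extraction
(FE) scanner files who want a transparent, scriptable alternative to
proprietary preprocessing: every step is a plain function over a probes ×
arrays matrix, and a synthetic scanner-file generator with known ground
truth makes the whole pipeline testable without real arrays.

## What it computes

* **Extraction** — parses the FEATURES block of FE text files (columns
  located by name), keeping per-channel median signals; non-positive or
  unparseable signals are dropped and reported, never clamped.
* **Preprocessing** — log2 transform; within-array averaging of replicated
  probes (the replicate spread is the intra-array error estimate); the
  negative-control probe `(-)3xSLv1` is collapsed alongside and kept as the
  background row.
* **Normalization** — each array `y` is corrected against the per-probe mean
  `x` of all arrays by subtracting the fitted deviation from identity,
  `ŷ = y − (f(x) − x)`, with `f` either a global OLS line or a locally
  weighted linear (LOESS) smooth at a scale of one tenth of the signal
  range; plain quantile normalization is included for comparison.
* **Variance statistics** — SD-vs-mean slope and R², a per-probe
  Shapiro-Wilk normality screen, genewise per-channel SDs, the Cy5:Cy3
  covariance and correlation, and the covariance-corrected SD of the
  log-ratio, `SD(E−R) = sqrt(SD_E² + SD_R² − 2·Cov)` — the quantity that
  says whether dividing by the reference channel actually reduces error.
* **Expressed-gene calling** — probe is "on" iff its log2 signal exceeds
  the negative-control background plus a threshold; sweeping the threshold
  yields a call curve, and an off-target (plant-RNA-style) synthetic sample
  bounds the false-positive rate. A per-bin interference analysis
  quantifies the coupling of large Cy5 signal changes into the Cy3 channel.
* **Classical MDS** — arrays embedded from their Euclidean distance matrix;
  dimensionality chosen as the smallest k whose cumulative eigenvalue mass
  `P_k = Σ_{i≤k} λ_i⁺ / Σ λ_i⁺` reaches 0.8.

## Worked example

```python
import numpy as np
import twocolorqc as tq
from twocolorqc.normalize import normalize_matrix

cfg = tq.SimConfig(seed=1)              # 2,000 probes, 20 arrays, known truth
ds  = tq.generate_dataset(cfg)
m3, _ = tq.build_matrix(ds.tables, "Cy3")
m5, _ = tq.build_matrix(ds.tables, "Cy5")
n3, _ = normalize_matrix(m3, "loess")
n5, _ = normalize_matrix(m5, "loess")

rep = tq.channel_stats(n5, n3)
print(round(m3.data.std(axis=1, ddof=1).mean(), 3))   # 0.43  raw Cy3 genewise SD
print(round(rep.summary["sd_cy3_mean"], 3))           # 0.236 after LOESS
print(round(rep.summary["cov_mean"], 3))              # 0.09  Cy5:Cy3 covariance
print(round(rep.summary["sd_diff_eq"], 3))            # 0.302 SD of the log-ratio

bg = tq.fit_background(n5)
frac = np.mean([tq.call_expressed(n5.data[a], bg, [0.5]).fraction_on[0]
                for a in n5.array_ids])
print(round(frac, 3))                                 # 0.677 probes on at +0.5
```

Reading the output: LOESS normalization brings the raw genewise Cy3 SD of
0.43 down to 0.236 log2 units — essentially the generator's injected
residual noise (0.24), i.e. the array biases are gone.  The recovered
channel covariance (0.09) feeds the ratio formula: the Cy5/Cy3 log-ratio
would have SD 0.302 against 0.463 for the normalized Cy5 signal alone, the
modest gain the covariance correction predicts.  At a cutoff of 0.5 log2
units above the negative-control background, 67.7% of probes are called
expressed, recovering the 65% of probes the generator planted as truly
expressed (the remainder is the leakage the noise model predicts); the same
call on the off-target synthetic sample stays below 5%.

The same pipeline runs from the shell:

```bash
twocolorqc simulate --n-probes 2000 --n-arrays 20 --seed 1 --outdir fe/
twocolorqc extract fe/array*.txt --outdir mat/
twocolorqc normalize --method loess --in mat/raw_cy3.tsv --out mat/norm_cy3.tsv
twocolorqc qc --cy5 mat/norm_cy5.tsv --cy3 mat/norm_cy3.tsv --out qc.tsv
twocolorqc run --config pipeline.yaml      # everything end to end
```

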