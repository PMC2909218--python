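"""Synthetic Agilent-style two-colour array generator with known truth.

The generator emulates the study design the pipeline targets: a catalogue of
unique 60-mer probes (41,001 at full scale, 2,000 by default for desk-scale
work) of which a fixed subset is spotted 10× per array, a negative-control
probe spotted 153×, raw signals spanning roughly 60–200,000 fluorescence
units, array-specific linear and quadratic biases on the log2 scale, and
jointly drawn Cy3/Cy5 noise with a configurable covariance.

Model, per probe p, array a, channel c (all on the log2 scale)::

    value = m_pc + o_a + (s_a - 1) * (m_pc - mu) + k_a * (m_pc - mu)^2 + eps

where ``m_pc`` is the probe's true mean (near background for non-expressed
probes), ``mu`` the design centre (``mean_log2``), ``(o_a, s_a, k_a)`` the
array's offset/slope/curvature bias, and ``eps`` bivariate Gaussian across
the two channels.  Replicated probes share one array-level value and add
independent within-array feature noise (its own, smaller, channel
covariance).  Values are exponentiated (``2**x``) into FE files.

Noise is Gaussian on the log2 scale — an explicit modelling assumption,
consistent with the observation that log2-transformed array data approximate
normality probe-by-probe far better than raw data do.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; the same config yields byte-identical FE files.
"""

from __future__ import annotations

import math
import os
from dataclasses import asdict, dataclass
import numpy as np
import pandas as pd
import yaml

from .io_agilent import FeatureTable, write_fe_file

__all__ = [
    "NEGATIVE_CONTROL",
    "ArrayBias",
    "SimConfig",
    "TruthTable",
    "SyntheticDataset",
    "generate_dataset",
    "generate_offdomain_sample",
]

#: Probe name of the negative-control oligonucleotide (spotted 153× per array).
NEGATIVE_CONTROL = "(-)3xSLv1"


@dataclass(frozen=True)
class ArrayBias:
    """Systematic per-array distortion on the log2 scale, about ``mean_log2``."""

    offset: float = 0.0
    slope: float = 1.0
    curvature: float = 0.0

    def apply(self, x: np.ndarray, centre: float) -> np.ndarray:
        c = x - centre
        return x + self.offset + (self.slope - 1.0) * c + self.curvature * c * c


IDENTITY_BIAS = ArrayBias()


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults are the desk-scale rendering of the emulated study: 2,000 unique
    probes (``full_scale()`` gives 41,001), 263 probes replicated 10×, the
    negative control spotted 153×, inter-array residual noise SDs of
    0.24 (Cy3) / 0.52 (Cy5) log2 units with channel covariance 0.09,
    within-array replicate noise of 0.16 / 0.20 with covariance 0.02, a
    background at log2(60) ≈ 5.91, and 65% of probes expressed.
    """

    n_probes: int = 2000
    n_replicate_probes: int = 263
    replicate_count: int = 10
    negative_control_count: int = 153
    n_arrays: int = 20
    mean_log2: float = 8.5
    probe_sd: float = 2.0
    noise_sd_cy3: float = 0.24
    noise_sd_cy5: float = 0.52
    channel_cov: float = 0.09
    tech_sd_cy5: float | None = None  # None: derived, see tech_bio_split()
    within_sd_cy3: float = 0.16
    within_sd_cy5: float = 0.20
    within_cov: float = 0.02
    offset_range: tuple[float, float] = (-0.5, 0.5)
    slope_range: tuple[float, float] = (0.9, 1.1)
    curvature_range: tuple[float, float] = (-0.01, 0.01)
    array_bias: tuple[ArrayBias, ...] | None = None
    expressed_fraction: float = 0.65
    stimulated_fraction: float = 0.0
    stimulation_effect: float = 2.0
    array_classes: tuple[str, ...] | None = None
    class_probe_fraction: float = 0.05
    class_effect: float = 1.5
    background_log2: float = math.log2(60.0)
    background_sd: float = 0.25
    control_probe: str = NEGATIVE_CONTROL
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_probes", "replicate_count", "negative_control_count", "n_arrays"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_replicate_probes <= self.n_probes:
            raise ValueError("n_replicate_probes must lie in [0, n_probes]")
        for name in ("expressed_fraction", "stimulated_fraction", "class_probe_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.channel_cov**2 > self.noise_sd_cy3**2 * self.noise_sd_cy5**2 + 1e-15:
            raise ValueError("channel_cov^2 exceeds noise_sd_cy3^2 * noise_sd_cy5^2")
        if self.within_cov**2 > self.within_sd_cy3**2 * self.within_sd_cy5**2 + 1e-15:
            raise ValueError("within_cov^2 exceeds within_sd_cy3^2 * within_sd_cy5^2")
        if self.array_bias is not None and len(self.array_bias) != self.n_arrays:
            raise ValueError("array_bias must list one ArrayBias per array")
        if self.array_classes is not None and len(self.array_classes) != self.n_arrays:
            raise ValueError("array_classes must list one label per array")

    def tech_bio_split(self) -> tuple[float, float]:
        """Decompose the Cy5 inter-array SD into technical and biological parts.

        ``noise_sd_cy5`` is the *total* per-array SD of an expressed probe's
        Cy5 signal.  Its technical component is shared with the reference
        channel (it is what carries ``channel_cov``) and affects every
        probe; the biological sample-to-sample component affects expressed
        probes only — a probe with no transcript has nothing biological to
        vary.  By default the technical SD is the smallest value consistent
        with the channel covariance (``channel_cov / noise_sd_cy3``, padded
        1% to keep the implied correlation below 1), or ``noise_sd_cy5``
        itself when that bound is not binding; the biological SD is the
        quadrature remainder.
        """
        if self.tech_sd_cy5 is not None:
            tech = self.tech_sd_cy5
        elif self.channel_cov != 0 and self.noise_sd_cy3 > 0:
            tech = min(self.noise_sd_cy5,
                       abs(self.channel_cov) / self.noise_sd_cy3 / 0.99)
        else:
            tech = self.noise_sd_cy5
        if tech > self.noise_sd_cy5 + 1e-12:
            raise ValueError("tech_sd_cy5 exceeds the total noise_sd_cy5")
        bio = math.sqrt(max(0.0, self.noise_sd_cy5**2 - tech**2))
        return tech, bio

    @classmethod
    def full_scale(cls, **overrides) -> "SimConfig":
        """The full array design: 41,001 unique probes."""
        overrides.setdefault("n_probes", 41001)
        return cls(**overrides)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["array_bias"] = (
            None if self.array_bias is None else [asdict(b) for b in self.array_bias]
        )
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("array_bias"):
            d["array_bias"] = tuple(ArrayBias(**b) for b in d["array_bias"])
        for key in ("offset_range", "slope_range", "curvature_range", "array_classes"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth behind a generated dataset.

    ``probes`` — one row per unique probe: true log2 means per channel
    (before array bias and before per-array effects), expressed flag,
    replicated flag, stimulated flag.
    ``arrays`` — one row per array: bias parameters, class label,
    stimulated flag.
    ``class_probes`` — class label → ids of the probes carrying that
    class's Cy5 effect.
    """

    probes: pd.DataFrame
    arrays: pd.DataFrame
    class_probes: dict[str, list[str]]
    config: SimConfig

    def __post_init__(self) -> None:
        if len(self.probes) != self.config.n_probes:
            raise ValueError("truth table must cover every generated probe")

    def true_matrix(self, channel: str) -> pd.DataFrame:
        """Noiseless biased log2 values, probes × arrays — what the pipeline
        would see with all noise SDs at zero."""
        base = self.probes[f"mean_{channel.lower()}"].to_numpy()
        cols = {}
        for row in self.arrays.itertuples():
            m = base.copy()
            if channel == "Cy5":
                m = m + self._cy5_effects(row)
            bias = ArrayBias(row.offset, row.slope, row.curvature)
            cols[row.array_id] = bias.apply(m, self.config.mean_log2)
        return pd.DataFrame(cols, index=self.probes.index)

    def _cy5_effects(self, array_row) -> np.ndarray:
        eff = np.zeros(len(self.probes))
        if array_row.stimulated:
            eff[self.probes["stimulated"].to_numpy()] += self.config.stimulation_effect
        label = array_row.array_class
        if label and label in self.class_probes:
            eff[self.probes.index.isin(self.class_probes[label])] += self.config.class_effect
        return eff

    def write(self, path: str | os.PathLike) -> None:
        self.probes.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


@dataclass
class SyntheticDataset:
    tables: list[FeatureTable]
    truth: TruthTable
    config: SimConfig

    def write(self, outdir: str | os.PathLike) -> list[str]:
        """Write FE files + truth + config; returns the FE file paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = []
        for t in self.tables:
            p = os.path.join(os.fspath(outdir), f"{t.array_id}.txt")
            write_fe_file(t, p)
            paths.append(p)
        self.truth.write(os.path.join(os.fspath(outdir), "truth_probes.tsv"))
        self.truth.arrays.to_csv(
            os.path.join(os.fspath(outdir), "truth_arrays.tsv"), sep="\t", index=False,
            float_format="%.17g",
        )
        self.config.to_yaml(os.path.join(os.fspath(outdir), "sim_config.yaml"))
        return paths


# ---------------------------------------------------------------------------


def _joint_noise(rng: np.random.Generator, n: int, sd3: float, sd5: float,
                 cov: float) -> tuple[np.ndarray, np.ndarray]:
    """n draws of (Cy3, Cy5) noise with the given SDs and covariance.

    Built from two independent standard normal vectors via the Cholesky
    factor, which degrades gracefully to independent (or zero) noise.
    """
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    e3 = sd3 * z1
    if sd3 > 0:
        rho = cov / (sd3 * sd5) if sd5 > 0 else 0.0
    else:
        rho = 0.0
    rho = float(np.clip(rho, -1.0, 1.0))
    e5 = sd5 * (rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
    return e3, e5


def _draw_probe_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"P{i:06d}" for i in range(cfg.n_probes)]
    expressed = np.zeros(cfg.n_probes, dtype=bool)
    n_expr = int(round(cfg.expressed_fraction * cfg.n_probes))
    expressed[rng.choice(cfg.n_probes, size=n_expr, replace=False)] = True

    # a non-transcribed probe's signal is pure background hybridisation:
    # its true mean sits at the background level, and only per-array noise
    # (and array bias) moves it
    means = np.full(cfg.n_probes, cfg.background_log2)
    # expressed probes sit clearly above background: truncated normal, lower
    # bound one log2 unit above the background mean
    lo = cfg.background_log2 + 1.0
    m = rng.normal(cfg.mean_log2, cfg.probe_sd, size=n_expr)
    for _ in range(1000):
        bad = m < lo
        if not bad.any():
            break
        m[bad] = rng.normal(cfg.mean_log2, cfg.probe_sd, size=int(bad.sum()))
    means[expressed] = np.maximum(m, lo)

    replicated = np.zeros(cfg.n_probes, dtype=bool)
    replicated[: cfg.n_replicate_probes] = True

    stimulated = np.zeros(cfg.n_probes, dtype=bool)
    if cfg.stimulated_fraction > 0:
        cand = np.flatnonzero(expressed)
        k = int(round(cfg.stimulated_fraction * cfg.n_probes))
        k = min(k, len(cand))
        stimulated[rng.choice(cand, size=k, replace=False)] = True

    return pd.DataFrame(
        {
            "mean_cy3": means,
            "mean_cy5": means.copy(),
            "expressed": expressed,
            "replicated": replicated,
            "stimulated": stimulated,
        },
        index=pd.Index(ids, name="probe_id"),
    )


def _draw_arrays(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"array{a:03d}" for a in range(cfg.n_arrays)]
    if cfg.array_bias is not None:
        biases = list(cfg.array_bias)
    else:
        biases = [
            ArrayBias(
                offset=rng.uniform(*cfg.offset_range),
                slope=rng.uniform(*cfg.slope_range),
                curvature=rng.uniform(*cfg.curvature_range),
            )
            for _ in ids
        ]
    stim_flags = [cfg.stimulated_fraction > 0 and a >= cfg.n_arrays // 2
                  for a in range(cfg.n_arrays)]
    classes = list(cfg.array_classes) if cfg.array_classes is not None else [""] * cfg.n_arrays
    return pd.DataFrame(
        {
            "array_id": ids,
            "offset": [b.offset for b in biases],
            "slope": [b.slope for b in biases],
            "curvature": [b.curvature for b in biases],
            "stimulated": stim_flags,
            "array_class": classes,
        }
    )


def _draw_class_probes(cfg: SimConfig, probes: pd.DataFrame,
                       rng: np.random.Generator) -> dict[str, list[str]]:
    if cfg.array_classes is None:
        return {}
    labels = sorted(set(cfg.array_classes))
    pool = list(probes.index[probes["expressed"].to_numpy()])
    per_class = int(round(cfg.class_probe_fraction * cfg.n_probes))
    out: dict[str, list[str]] = {}
    for lab in labels:
        take = min(per_class, len(pool))
        chosen = rng.choice(len(pool), size=take, replace=False)
        chosen_ids = [pool[i] for i in sorted(chosen)]
        out[lab] = chosen_ids
        pool = [p for p in pool if p not in set(chosen_ids)]
    return out


def generate_dataset(cfg: SimConfig, outdir: str | os.PathLike | None = None
                     ) -> SyntheticDataset:
    """Generate one set of FE-format arrays plus its truth table.

    Per array, per channel: probe means are distorted by the array's bias,
    jointly-Gaussian channel noise is added, replicate probes are expanded to
    ``replicate_count`` features with extra within-array noise, the negative
    control is spotted ``negative_control_count`` times around the
    background, and values are exponentiated into raw FE signals.

    If ``outdir`` is given the FE files, truth tables and config are written
    there as well.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    probes = _draw_probe_truth(cfg, rng)
    arrays = _draw_arrays(cfg, rng)
    class_probes = _draw_class_probes(cfg, probes, rng)
    truth = TruthTable(probes=probes, arrays=arrays, class_probes=class_probes, config=cfg)

    true3 = truth.true_matrix("Cy3")
    true5 = truth.true_matrix("Cy5")

    rep_mask = probes["replicated"].to_numpy()
    expr_mask = probes["expressed"].to_numpy()
    tech5, bio5 = cfg.tech_bio_split()
    tables = []
    for ai, row in enumerate(arrays.itertuples()):
        m3 = true3[row.array_id].to_numpy()
        m5 = true5[row.array_id].to_numpy()
        e3, e5 = _joint_noise(rng, cfg.n_probes, cfg.noise_sd_cy3, tech5,
                              cfg.channel_cov)
        if bio5 > 0:
            # biological sample-to-sample variation: expressed probes only
            e5 = e5 + bio5 * rng.standard_normal(cfg.n_probes) * expr_mask
        arr3 = m3 + e3
        arr5 = m5 + e5

        names: list[str] = []
        ctypes: list[int] = []
        g: list[np.ndarray] = []
        r: list[np.ndarray] = []

        # singleton probes: one feature each
        single = ~rep_mask
        names.extend(probes.index[single])
        ctypes.extend([0] * int(single.sum()))
        g.append(arr3[single])
        r.append(arr5[single])

        # replicated probes: replicate_count features sharing the array-level
        # value, plus within-array feature noise
        n_rep = int(rep_mask.sum())
        if n_rep:
            w3, w5 = _joint_noise(rng, n_rep * cfg.replicate_count,
                                  cfg.within_sd_cy3, cfg.within_sd_cy5, cfg.within_cov)
            rep3 = np.repeat(arr3[rep_mask], cfg.replicate_count) + w3
            rep5 = np.repeat(arr5[rep_mask], cfg.replicate_count) + w5
            names.extend(np.repeat(probes.index[rep_mask].to_numpy(), cfg.replicate_count))
            ctypes.extend([0] * (n_rep * cfg.replicate_count))
            g.append(rep3)
            r.append(rep5)

        # negative-control features, drawn around the (biased) background
        bias = ArrayBias(row.offset, row.slope, row.curvature)
        bg = float(bias.apply(np.array([cfg.background_log2]), cfg.mean_log2)[0])
        c3 = bg + rng.normal(0.0, cfg.background_sd, size=cfg.negative_control_count)
        c5 = bg + rng.normal(0.0, cfg.background_sd, size=cfg.negative_control_count)
        names.extend([cfg.control_probe] * cfg.negative_control_count)
        ctypes.extend([-1] * cfg.negative_control_count)
        g.append(c3)
        r.append(c5)

        glog = np.concatenate(g)
        rlog = np.concatenate(r)
        frame = pd.DataFrame(
            {
                "feature_index": np.arange(len(names)),
                "probe_name": names,
                "control_type": ctypes,
                "g_median_signal": np.exp2(glog),
                "r_median_signal": np.exp2(rlog),
            }
        )
        tables.append(FeatureTable(array_id=row.array_id, frame=frame))

    ds = SyntheticDataset(tables=tables, truth=truth, config=cfg)
    if outdir is not None:
        ds.write(outdir)
    return ds


def generate_offdomain_sample(
    cfg: SimConfig,
    elevated_fraction: float = 0.02,
    elevation: float = 1.5,
    array_id: str = "offdomain000",
    seed: int | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Emulate an off-target hybridisation (e.g. plant RNA on a human array).

    At the default ``elevated_fraction`` at least 95% of experimental probes
    draw straight from the negative-control background distribution;
    ``elevated_fraction`` of them are elevated by ``elevation`` log2 units
    (weak residual cross-hybridisation; settable up to 1.0 for boundary
    checks).  Returns the FeatureTable and a per-probe truth frame (columns
    ``true_mean``, ``elevated``).
    """
    if not 0.0 <= elevated_fraction <= 1.0:
        raise ValueError("elevated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    ids = [f"P{i:06d}" for i in range(cfg.n_probes)]
    elevated = np.zeros(cfg.n_probes, dtype=bool)
    k = int(round(elevated_fraction * cfg.n_probes))
    if k:
        elevated[rng.choice(cfg.n_probes, size=k, replace=False)] = True
    means = np.full(cfg.n_probes, cfg.background_log2)
    means[elevated] += elevation

    log3 = means + rng.normal(0.0, cfg.background_sd, size=cfg.n_probes)
    log5 = means + rng.normal(0.0, cfg.background_sd, size=cfg.n_probes)
    c3 = cfg.background_log2 + rng.normal(0.0, cfg.background_sd,
                                          size=cfg.negative_control_count)
    c5 = cfg.background_log2 + rng.normal(0.0, cfg.background_sd,
                                          size=cfg.negative_control_count)

    names = ids + [cfg.control_probe] * cfg.negative_control_count
    ctypes = [0] * cfg.n_probes + [-1] * cfg.negative_control_count
    frame = pd.DataFrame(
        {
            "feature_index": np.arange(len(names)),
            "probe_name": names,
            "control_type": ctypes,
            "g_median_signal": np.exp2(np.concatenate([log3, c3])),
            "r_median_signal": np.exp2(np.concatenate([log5, c5])),
        }
    )
    truth = pd.DataFrame({"true_mean": means, "elevated": elevated},
                         index=pd.Index(ids, name="probe_id"))
    return FeatureTable(array_id=array_id, frame=frame), truth
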