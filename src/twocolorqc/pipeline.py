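"""End-to-end orchestration: extract → collapse → normalize → QC → call → MDS.

One plain-text YAML config drives a run; every tabular output is TSV with a
provenance comment header (package version, seed, config hash) so that a
fixed config and seed reproduce byte-identical outputs.  Any stage failure
aborts with the stage name.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression_call import call_expressed, fit_background
from .io_agilent import ExpressionMatrix, FeatureTable, read_fe_file, write_matrix
from .mds import classical_mds, distance_matrix
from .normalize import models_to_frame, normalize_matrix
from .preprocess import build_matrix
from .synthetic import NEGATIVE_CONTROL, SimConfig, generate_dataset
from .variance import channel_stats, normality_screen, sd_vs_mean

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("twocolorqc")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and file if relevant)."""


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    inputs: tuple[str, ...] | None = None  # FE file paths; or simulate instead
    simulate: SimConfig | None = None
    method: str = "loess"
    segments: int = 10
    leave_one_out: bool = False
    thresholds: tuple[float, ...] = tuple(
        float(t) for t in np.round(np.arange(0.0, 1.01, 0.1), 10)
    )
    k_max: int = 10
    cutoff: float = 0.8
    control_probe: str = NEGATIVE_CONTROL
    run_normality_screen: bool = True
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if raw.get("simulate") is not None and not isinstance(raw["simulate"], SimConfig):
            sim = dict(raw["simulate"])
            sim.setdefault("seed", raw.get("seed", 0))
            raw["simulate"] = SimConfig.from_dict(sim)
        if raw.get("inputs") is not None:
            raw["inputs"] = tuple(raw["inputs"])
        if raw.get("thresholds") is not None:
            raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)  # analysis parameters only, not run location
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> list[str]:
        return [
            f"twocolorqc {__version__}",
            f"seed={self.seed} config_sha={self.config_hash()}",
        ]


def _write_tsv(df: pd.DataFrame, path: str, header_lines: Sequence[str],
               index_label: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label, float_format="%.17g", lineterminator="\n")


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Run every stage; returns a map of output name → file path."""
    os.makedirs(cfg.outdir, exist_ok=True)
    prov = cfg.provenance()
    outputs: dict[str, str] = {}
    run_log: list[str] = list(prov)

    def out(name: str, filename: str) -> str:
        path = os.path.join(cfg.outdir, filename)
        outputs[name] = path
        return path

    def stage(name: str):
        def wrap(fn):
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            run_log.append(f"stage {name}: ok")
            log.info("stage %s: ok", name)
            return result

        return wrap

    # -- extract ------------------------------------------------------------
    @stage("extract")
    def tables() -> list[FeatureTable]:
        if cfg.simulate is not None:
            ds = generate_dataset(cfg.simulate, outdir=os.path.join(cfg.outdir, "fe_files"))
            return ds.tables
        if not cfg.inputs:
            raise PipelineError("stage 'extract' failed: no inputs and no simulate block")
        loaded = []
        for path in cfg.inputs:
            if not os.path.exists(path):
                raise PipelineError(f"stage 'extract' failed: input not found: {path}")
            t = read_fe_file(path)
            if t.report is not None:
                run_log.extend(t.report.log_lines())
            loaded.append(t)
        return loaded

    # -- collapse / log2 ----------------------------------------------------
    @stage("collapse")
    def matrices() -> dict[str, ExpressionMatrix]:
        out_m = {}
        for channel in ("Cy3", "Cy5"):
            m, rep = build_matrix(tables, channel, cfg.control_probe)
            out_m[channel] = m
            write_matrix(m, out(f"raw_{channel.lower()}", f"raw_{channel.lower()}.tsv"),
                         header_lines=prov + [f"stage=collapse channel={channel}"])
            _write_tsv(rep, out(f"replicates_{channel.lower()}",
                                f"replicates_{channel.lower()}.tsv"),
                       prov + [f"stage=collapse channel={channel}"])
        return out_m

    # -- normalize ----------------------------------------------------------
    @stage("normalize")
    def normalized() -> dict[str, ExpressionMatrix]:
        out_m = {}
        for channel in ("Cy3", "Cy5"):
            norm, models = normalize_matrix(
                matrices[channel], method=cfg.method, segments=cfg.segments,
                leave_one_out=cfg.leave_one_out,
            )
            out_m[channel] = norm
            write_matrix(norm, out(f"norm_{channel.lower()}", f"norm_{channel.lower()}.tsv"),
                         header_lines=prov + [f"stage=normalize method={cfg.method}"])
            _write_tsv(models_to_frame(models),
                       out(f"models_{channel.lower()}", f"models_{channel.lower()}.tsv"),
                       prov + [f"stage=normalize method={cfg.method}"])
        return out_m

    # -- QC ------------------------------------------------------------------
    @stage("qc")
    def qc_report():
        report = channel_stats(normalized["Cy5"], normalized["Cy3"])
        fit_raw = sd_vs_mean(matrices["Cy3"])
        fit_norm = sd_vs_mean(normalized["Cy3"])
        report.summary["sd_vs_mean_slope_raw"] = fit_raw.slope
        report.summary["sd_vs_mean_r2_raw"] = fit_raw.r_squared
        report.summary["sd_vs_mean_slope_norm"] = fit_norm.slope
        report.summary["sd_vs_mean_r2_norm"] = fit_norm.r_squared
        if cfg.run_normality_screen:
            screen = normality_screen(normalized["Cy3"])
            report.summary["normality_fraction"] = screen.fraction_passing
            report.summary["normality_fraction_bh"] = screen.fraction_passing_bh
        report.to_tsv(out("variance_report", "variance_report.tsv"),
                      header_lines=prov + ["stage=qc"])
        return report

    # -- calling ------------------------------------------------------------
    @stage("call")
    def curves():
        bg = fit_background(normalized["Cy5"], control_probe=cfg.control_probe)
        frames = []
        for array_id in normalized["Cy5"].array_ids:
            col = normalized["Cy5"].data[array_id]
            curve = call_expressed(col, bg, cfg.thresholds)
            f = curve.to_frame()
            f.insert(0, "array_id", array_id)
            frames.append(f)
        allc = pd.concat(frames, ignore_index=True)
        mean_curve = allc.groupby("threshold", sort=True)["fraction_on"].mean().reset_index()
        _write_tsv(allc, out("call_curves", "call_curves.tsv"), prov + ["stage=call"])
        _write_tsv(mean_curve, out("call_curve_mean", "call_curve_mean.tsv"),
                   prov + ["stage=call"])
        return allc

    # -- MDS -----------------------------------------------------------------
    @stage("mds")
    def mds_result():
        expr = normalized["Cy5"].drop_probes([cfg.control_probe])
        D = distance_matrix(expr)
        result = classical_mds(D, k_max=cfg.k_max, cutoff=cfg.cutoff)
        _write_tsv(result.coordinates, out("mds_scores", "mds_scores.tsv"),
                   prov + [f"stage=mds selected_k={result.selected_k}"],
                   index_label="array_id")
        eig = pd.DataFrame(
            {
                "dimension": np.arange(1, len(result.eigenvalues) + 1),
                "eigenvalue": result.eigenvalues,
                "p_k": np.append(result.p_k, np.nan)[: len(result.eigenvalues)],
            }
        )
        _write_tsv(eig, out("mds_eigenvalues", "mds_eigenvalues.tsv"),
                   prov + [f"stage=mds selected_k={result.selected_k}"])
        return result

    run_log.append(f"selected_k={mds_result.selected_k}")
    log_path = out("run_log", "run_log.txt")
    with open(log_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(run_log) + "\n")
    return outputs
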