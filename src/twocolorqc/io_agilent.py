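"""Reading Agilent Feature Extraction (FE) scanner output and signal matrices.

FE files are tab-delimited text with several header stanzas (TYPE, FEPARAMS,
STATS, ...) followed by a FEATURES block: a line whose first field is the
token ``FEATURES`` carries the column names, and the rows that follow
(conventionally prefixed with ``DATA``) carry one spotted feature each.  Only
the FEATURES block is consumed; columns are located by name so the parser is
independent of column order and of FE software version, and unknown columns
are ignored.

Only the per-channel *median* signals are used downstream.  Features whose
signal fields do not parse as positive numbers are dropped and counted in a
:class:`ParseReport` — log2 transformation downstream requires strictly
positive signal, and silently clamping would bias the background estimate.

Processed matrices travel as plain TSV (UTF-8, '.' decimal, no quoting,
``%.17g`` floats) so that a write/read round trip is bit-exact.
"""

from __future__ import annotations

import io
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "FEParseError",
    "FeatureRecord",
    "ParseReport",
    "FeatureTable",
    "ExpressionMatrix",
    "read_fe_file",
    "write_fe_file",
    "read_matrix",
    "write_matrix",
]

#: FE column names the parser must find in the FEATURES header.
REQUIRED_COLUMNS = ("ProbeName", "ControlType", "gMedianSignal", "rMedianSignal")

#: Stanza tokens that terminate the FEATURES block if encountered again.
_STANZA_TOKENS = {"TYPE", "FEPARAMS", "STATS", "FEATURES"}

_FLOAT_FMT = "%.17g"


class FEParseError(ValueError):
    """Raised when an FE file lacks the FEATURES block, a required column,
    or any usable data row."""


@dataclass(frozen=True)
class FeatureRecord:
    """One spotted feature of one scanned array.

    ``control_type`` follows the FE convention: 0 for experimental probes,
    nonzero for Agilent control features.  Signals are raw fluorescence
    (arbitrary units), strictly positive after parsing.
    """

    feature_index: int
    probe_name: str
    control_type: int
    g_median_signal: float
    r_median_signal: float


@dataclass
class ParseReport:
    """Bookkeeping for one FE parse: rows seen, kept, dropped and why."""

    path: str
    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    reasons: Counter = field(default_factory=Counter)

    def log_lines(self) -> list[str]:
        lines = [
            f"{self.path}: {self.n_rows} feature rows, {self.n_kept} kept, "
            f"{self.n_dropped} dropped"
        ]
        for reason, count in sorted(self.reasons.items()):
            lines.append(f"{self.path}:   dropped {count} ({reason})")
        return lines


@dataclass
class FeatureTable:
    """All parsed features of one array, stored columnar for speed.

    ``frame`` has the columns ``feature_index``, ``probe_name``,
    ``control_type``, ``g_median_signal``, ``r_median_signal``.
    """

    array_id: str
    frame: pd.DataFrame
    report: ParseReport | None = None

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise FEParseError(f"array {self.array_id!r}: no feature records")
        if not self.array_id:
            raise ValueError("array_id must be non-empty")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> Iterator[FeatureRecord]:
        for row in self.frame.itertuples(index=False):
            yield FeatureRecord(
                int(row.feature_index),
                str(row.probe_name),
                int(row.control_type),
                float(row.g_median_signal),
                float(row.r_median_signal),
            )

    def signals(self, channel: str) -> pd.Series:
        """Raw signals of one channel, indexed by probe name (duplicates kept)."""
        col = _channel_column(channel)
        return pd.Series(
            self.frame[col].to_numpy(), index=self.frame["probe_name"], name=self.array_id
        )


def _channel_column(channel: str) -> str:
    if channel == "Cy3":
        return "g_median_signal"
    if channel == "Cy5":
        return "r_median_signal"
    raise ValueError(f"channel must be 'Cy3' or 'Cy5', got {channel!r}")


@dataclass
class ExpressionMatrix:
    """Probes × arrays matrix of one channel's signal (log2 unless stated).

    Thin wrapper over a :class:`pandas.DataFrame` whose index is unique probe
    ids and whose columns are unique array ids; values must be finite.
    """

    data: pd.DataFrame
    channel: str = "Cy3"

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("ExpressionMatrix must have at least one probe and one array")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated probe ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicated array ids")
        self.data = self.data.astype(float)
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("ExpressionMatrix values must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.data.shape[1]

    def drop_probes(self, probes: Iterable[str]) -> "ExpressionMatrix":
        keep = self.data.index.difference(pd.Index(probes))
        return ExpressionMatrix(self.data.loc[self.data.index.intersection(keep, sort=False)],
                                channel=self.channel)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), channel=self.channel)


# ---------------------------------------------------------------------------
# FE files


def read_fe_file(path: str | os.PathLike, array_id: str | None = None) -> FeatureTable:
    """Parse one Agilent Feature Extraction text file.

    Locates the FEATURES header line, resolves the required columns by name,
    and returns one record per data row.  Rows whose signals are missing,
    non-numeric or ≤ 0 are dropped and tallied in ``table.report``.

    Raises
    ------
    FEParseError
        If the FEATURES block or any required column is missing, or no data
        row survives parsing.
    """
    path = os.fspath(path)
    if array_id is None:
        array_id = os.path.splitext(os.path.basename(path))[0]

    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    header: list[str] | None = None
    data_rows: list[list[str]] = []
    in_features = False
    for line in lines:
        if not line:
            continue
        fields = line.split("\t")
        token = fields[0]
        if not in_features:
            if token == "FEATURES":
                header = fields[1:]
                in_features = True
            continue
        if token == "DATA":
            data_rows.append(fields[1:])
        elif token == "*":
            break
        elif token in _STANZA_TOKENS:
            break
        elif header is not None and len(fields) == len(header):
            # dialect without the DATA prefix
            data_rows.append(fields)
        else:
            break

    if header is None:
        raise FEParseError(f"{path}: no FEATURES block found")
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise FEParseError(f"{path}: FEATURES block lacks required column {col!r}")
    if not data_rows:
        raise FEParseError(f"{path}: FEATURES block has zero data rows")

    raw = pd.DataFrame(data_rows, columns=header)
    report = ParseReport(path=path, n_rows=len(raw))

    probe = raw["ProbeName"].astype(str)
    ctype = pd.to_numeric(raw["ControlType"], errors="coerce")
    gsig = pd.to_numeric(raw["gMedianSignal"], errors="coerce")
    rsig = pd.to_numeric(raw["rMedianSignal"], errors="coerce")

    bad_probe = (probe.str.len() == 0).to_numpy()
    bad_ctype = ctype.isna().to_numpy()
    bad_parse = (gsig.isna() | rsig.isna()).to_numpy() & ~bad_ctype
    bad_sign = ((gsig <= 0) | (rsig <= 0)).fillna(False).to_numpy()
    report.reasons.update(
        {
            k: int(v)
            for k, v in {
                "empty probe name": bad_probe.sum(),
                "non-numeric control type": bad_ctype.sum(),
                "non-numeric signal": bad_parse.sum(),
                "non-positive signal": bad_sign.sum(),
            }.items()
            if v
        }
    )
    bad = bad_probe | bad_ctype | bad_parse | bad_sign
    report.n_dropped = int(bad.sum())
    report.n_kept = int((~bad).sum())
    if report.n_kept == 0:
        raise FEParseError(f"{path}: all {report.n_rows} feature rows unparseable")

    if "FeatureNum" in header:
        fnum = pd.to_numeric(raw["FeatureNum"], errors="coerce")
        fnum = fnum.fillna(pd.Series(range(len(raw)), index=raw.index))
    else:
        fnum = pd.Series(range(len(raw)), index=raw.index, dtype=float)

    keep = ~bad
    frame = pd.DataFrame(
        {
            "feature_index": fnum[keep].astype(int).to_numpy(),
            "probe_name": probe[keep].to_numpy(),
            "control_type": ctype[keep].astype(int).to_numpy(),
            "g_median_signal": gsig[keep].to_numpy(float),
            "r_median_signal": rsig[keep].to_numpy(float),
        }
    )
    return FeatureTable(array_id=array_id, frame=frame, report=report)


def write_fe_file(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write a FeatureTable back out in the FE dialect ``read_fe_file`` accepts.

    Signals are written with 17 significant digits so a round trip preserves
    them bit-exactly.
    """
    buf = io.StringIO()
    buf.write("TYPE\ttext\ttext\n")
    buf.write(f"FEPARAMS\tScan_ScannerName\tGrid_Name\nDATA\tsynthetic\t{table.array_id}\n*\n")
    buf.write("FEATURES\tFeatureNum\tProbeName\tControlType\tgMedianSignal\trMedianSignal\n")
    for row in table.frame.itertuples(index=False):
        buf.write(
            "DATA\t%d\t%s\t%d\t%s\t%s\n"
            % (
                row.feature_index,
                row.probe_name,
                row.control_type,
                _FLOAT_FMT % row.g_median_signal,
                _FLOAT_FMT % row.r_median_signal,
            )
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# signal matrices


def write_matrix(
    m: ExpressionMatrix,
    path: str | os.PathLike,
    header_lines: Sequence[str] = (),
) -> None:
    """Write an ExpressionMatrix as TSV (probe id column, array-id header).

    Optional ``header_lines`` are emitted as ``#``-prefixed comments before
    the table (used by the pipeline for provenance stamps).
    """
    if m.data.size == 0:
        raise ValueError("refusing to write an empty matrix")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        m.data.to_csv(fh, sep="\t", index_label="probe_id", float_format=_FLOAT_FMT,
                      lineterminator="\n")


def read_matrix(path: str | os.PathLike, channel: str = "Cy3") -> ExpressionMatrix:
    """Read a TSV signal matrix written by :func:`write_matrix`.

    ``#`` comment lines are skipped.  Duplicate probe ids or an empty table
    are fatal.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{os.fspath(path)}: empty matrix")
    if df.index.has_duplicates:
        raise ValueError(f"{os.fspath(path)}: duplicate probe ids on read")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, channel=channel)
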