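"""Plain-text I/O with strict, line-numbered schema validation.

Formats:

* timeseries — TSV, first row ROI labels, subsequent rows frames;
* manifest — CSV with leading ``# key: value`` config-echo comment lines and
  the fixed subject/session/score column set;
* connectivity matrices — TSV with ROI labels as header row and first column;
* metric and screen tables — plain TSV via pandas.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, RoiTimeseries

__all__ = [
    "MANIFEST_COLUMNS",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "read_fc",
    "write_fc",
    "read_table",
    "write_table",
    "write_cohort",
]

MANIFEST_COLUMNS = (
    "subject_id", "group", "session", "file", "age", "gender",
    "LSAS", "BFNE", "SIAS", "RSES", "HADS_A", "HADS_D", "completer",
)

_NUMERIC_MANIFEST = ("age", "LSAS", "BFNE", "SIAS", "RSES", "HADS_A", "HADS_D")


def write_timeseries(ts: RoiTimeseries, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ts.roi_labels) + "\n")
        for row in ts.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_timeseries(path, subject_id: str = "", session: str = "baseline") -> RoiTimeseries:
    """Read a label-headed TSV timeseries; errors carry row/column locations."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(labels):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(labels)} columns, got {len(fields)}"
                )
            try:
                vals = [float(x) for x in fields]
            except ValueError:
                bad = next(i for i, x in enumerate(fields) if not _is_float(x))
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {fields[bad]!r} in "
                    f"column {bad + 1} ({labels[bad]})"
                ) from None
            for col, v in enumerate(vals):
                if not np.isfinite(v):
                    raise ValueError(
                        f"{path}:{lineno}: non-finite value in column {col + 1} "
                        f"({labels[col]})"
                    )
            rows.append(vals)
    return RoiTimeseries(
        values=np.array(rows), roi_labels=labels, subject_id=subject_id, session=session
    )


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_manifest(manifest: pd.DataFrame, path, config_echo: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if config_echo:
        for key, value in config_echo.items():
            buf.write(f"# {key}: {value}\n")
    manifest.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def read_manifest(path) -> tuple[pd.DataFrame, dict]:
    """Read and validate a cohort manifest; returns (table, config echo)."""
    path = Path(path)
    echo: dict[str, str] = {}
    n_comment = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                echo[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")

    def _line(i: int) -> int:  # 1-based file line of data row i
        return n_comment + 2 + i

    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {missing}")
    dup = df.duplicated(subset=["subject_id", "session"])
    if dup.any():
        lines = [_line(i) for i in df.index[dup]]
        raise ValueError(f"{path}: duplicate subject-session rows at line(s) {lines}")
    bad_sess = ~df["session"].isin(("baseline", "followup"))
    if bad_sess.any():
        i = df.index[bad_sess][0]
        raise ValueError(
            f"{path}:{_line(i)}: unknown session {df.loc[i, 'session']!r}"
        )
    bad_grp = ~df["group"].isin(("control", "experimental"))
    if bad_grp.any():
        i = df.index[bad_grp][0]
        raise ValueError(f"{path}:{_line(i)}: unknown group {df.loc[i, 'group']!r}")
    for col in _NUMERIC_MANIFEST:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            i = df.index[bad][0]
            raise ValueError(
                f"{path}:{_line(i)}: non-numeric value {df.loc[i, col]!r} in column {col!r}"
            )
        df[col] = vals
    df["completer"] = df["completer"].astype(bool)
    return df, echo


def write_fc(fc: ConnectivityMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(("region",) + tuple(fc.roi_labels)) + "\n")
        for label, row in zip(fc.roi_labels, fc.r):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_fc(path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = tuple(df.columns)
    if tuple(df.index) != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return ConnectivityMatrix(r=df.to_numpy(dtype=float), roi_labels=labels)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"threshold": str}, float_precision="round_trip"
    )


def write_cohort(cohort, outdir) -> Path:
    """Write a generated cohort (manifest + timeseries TSVs) to a directory."""
    outdir = Path(outdir)
    for (sid, session), ts in cohort.timeseries.items():
        write_timeseries(ts, outdir / "timeseries" / f"{sid}_{session}.tsv")
    write_manifest(
        cohort.manifest, outdir / "manifest.csv", config_echo=cohort.config.to_dict()
    )
    return outdir / "manifest.csv"
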