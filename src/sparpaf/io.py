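"""Reading and writing signals and cohort manifests.

The native interchange format is a plain two-column text file per record —
time in seconds and amplitude in arbitrary units, with an optional header
line and comma/tab/space delimiters — plus a cohort manifest table
(``subject_id``, ``label``, ``fs``, ``sign_flipped``, ``file``).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SignalFormatError
from .synthetic import EcgSignal

__all__ = ["read_ecg", "write_ecg", "write_cohort", "read_cohort"]

_DELIMS = (",", "\t", None)  # None = any whitespace


def write_ecg(path: str | os.PathLike, signal: EcgSignal, delimiter: str = ",") -> None:
    """Write a record as two-column text (time_s, amplitude)."""
    t = signal.time
    header = f"time_s{delimiter}amplitude"
    np.savetxt(
        path,
        np.column_stack([t, signal.samples]),
        fmt=("%.6f", "%.8g"),
        delimiter=delimiter,
        header=header,
        comments="",
    )


def read_ecg(
    path: str | os.PathLike,
    format: str = "text",
    subject_id: str | None = None,
    label: str = "unknown",
) -> EcgSignal:
    """Read a single-lead ECG record.

    ``format="text"`` parses two-column (time_s, amplitude) files with an
    optional header; the delimiter is auto-detected among comma, tab and
    whitespace.  The sampling rate is inferred from the median time step and
    the time column must increase uniformly.
    """
    if format == "wfdb":
        raise SignalFormatError("WFDB input is not supported; convert to two-column text")
    if format != "text":
        raise SignalFormatError(f"unknown signal format {format!r}")
    path = Path(path)
    try:
        raw = path.read_text()
    except OSError as exc:
        raise SignalFormatError(f"cannot read {path}: {exc}") from exc

    lines = raw.splitlines()
    start = 0
    if lines and not _is_numeric_row(lines[0]):
        start = 1
    delim_used = None
    data = None
    for delim in _DELIMS:
        try:
            data = np.loadtxt(lines[start:], delimiter=delim, ndmin=2)
            delim_used = delim
            break
        except ValueError:
            continue
    if data is None or data.shape[1] < 2:
        raise SignalFormatError(f"{path}: could not parse two numeric columns (line {start + 1})")

    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if (dt <= 0).any():
        bad = int(np.flatnonzero(dt <= 0)[0]) + start + 2
        raise SignalFormatError(f"{path}: time column not strictly increasing at line {bad}")
    med = float(np.median(dt))
    if med <= 0 or not np.isfinite(med) or np.max(np.abs(dt - med)) > 0.01 * med:
        raise SignalFormatError(f"{path}: cannot infer a uniform sampling rate")
    fs = round(1.0 / med, 6)
    del delim_used
    return EcgSignal(
        subject_id=subject_id or path.stem,
        label=label,
        fs=float(fs),
        samples=np.asarray(x, dtype=np.float64),
    )


def _is_numeric_row(line: str) -> bool:
    for delim in (",", "\t", None):
        parts = line.split(delim) if delim else line.split()
        if len(parts) >= 2:
            try:
                float(parts[0]), float(parts[1])
                return True
            except ValueError:
                continue
    return False


def write_cohort(records: list[EcgSignal], outdir: str | os.PathLike) -> pd.DataFrame:
    """Write every record plus a ``manifest.csv``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}.csv"
        write_ecg(outdir / fname, rec)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "fs": rec.fs,
                "sign_flipped": rec.sign_flipped,
                "file": fname,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_cohort(outdir: str | os.PathLike) -> list[EcgSignal]:
    """Load a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        rec = read_ecg(outdir / row["file"], subject_id=row["subject_id"], label=row["label"])
        rec.sign_flipped = bool(row["sign_flipped"])
        records.append(rec)
    return records
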