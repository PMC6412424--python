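"""Reading and writing ECG signals and annotations.

Supported formats:

* WFDB records (PhysioNet ``.hea`` header + ``.dat`` signal), read-only
  for signal formats 16 and 212 — the formats the ECG-ID database uses —
  plus a format-16 writer for round-trip testing.  Samples are converted
  to physical units via the per-signal gain and baseline.
* Delimited text (comma-separated, ``.`` decimal): one voltage column, or
  time + voltage with the sampling frequency inferred from the median
  time spacing.
* Annotation tables: ``record_id,label,sample_index,time_s,amplitude_mV``.

Sample indices are 0-based; times in seconds are ``index / fs``.
"""
from __future__ import annotations

import csv
import re
from os import PathLike
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .types import LABELS, EcgSignal, FiducialAnnotation

__all__ = [
    "EcgSignal",
    "FiducialAnnotation",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_delimited",
    "write_delimited",
    "read_annotations",
    "write_annotations",
    "read_signal",
]

_ANNOTATION_COLUMNS = ["record_id", "label", "sample_index", "time_s", "amplitude_mV"]

# "filename format[xN][:N][+N] gain[(baseline)][/units] [adc_res [adc_zero ...]]"
_SIGNAL_LINE = re.compile(
    r"^(?P<fname>\S+)\s+(?P<fmt>\d+)(?:x\d+)?(?::\d+)?(?:\+\d+)?"
    r"(?:\s+(?P<gain>[-\d.eE]+)(?:\((?P<baseline>-?\d+)\))?(?:/(?P<units>\S+))?)?"
    r"(?:\s+(?P<adcres>\d+))?(?:\s+(?P<adczero>-?\d+))?"
)


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise FormatError(f"{hea_path}: empty WFDB header")
    rec = lines[0].split()
    if len(rec) < 2:
        raise FormatError(f"{hea_path}: malformed record line {lines[0]!r}")
    try:
        name = rec[0].split("/")[0]
        n_sig = int(rec[1])
        fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
        n_samp = int(rec[3]) if len(rec) > 3 else 0
    except ValueError as exc:
        raise FormatError(f"{hea_path}: malformed record line {lines[0]!r}") from exc
    if len(lines) < 1 + n_sig:
        raise FormatError(f"{hea_path}: expected {n_sig} signal lines")
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        m = _SIGNAL_LINE.match(ln)
        if not m:
            raise FormatError(f"{hea_path}: malformed signal line {ln!r}")
        gain = float(m.group("gain")) if m.group("gain") else 0.0
        if gain == 0.0:
            gain = 200.0  # WFDB default adu/physical-unit
        adczero = int(m.group("adczero")) if m.group("adczero") else 0
        baseline = int(m.group("baseline")) if m.group("baseline") else adczero
        sigs.append(
            {
                "fname": m.group("fname"),
                "fmt": int(m.group("fmt")),
                "gain": gain,
                "baseline": baseline,
            }
        )
    return name, n_sig, fs, n_samp, sigs


def _decode_dat(raw: bytes, fmt: int, n_sig: int) -> np.ndarray:
    """Digital samples, shape (n_frames, n_sig), formats 16 and 212."""
    if fmt == 16:
        d = np.frombuffer(raw, dtype="<i2")
        n_frames = d.size // n_sig
        return d[: n_frames * n_sig].reshape(n_frames, n_sig).astype(np.int32)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        n_triplets = b.size // 3
        b = b[: n_triplets * 3].reshape(n_triplets, 3).astype(np.int32)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        s2 = np.where(s2 > 2047, s2 - 4096, s2)
        flat = np.empty(2 * n_triplets, dtype=np.int32)
        flat[0::2] = s1
        flat[1::2] = s2
        n_frames = flat.size // n_sig
        return flat[: n_frames * n_sig].reshape(n_frames, n_sig)
    raise FormatError(f"unsupported WFDB signal format {fmt} (supported: 16, 212)")


def read_wfdb_record(path: str | PathLike, channel: int = 0) -> EcgSignal:
    """Read one channel of a WFDB record into physical units (mV).

    ``path`` may point at the ``.hea`` file or be the record path without
    extension.  All signals of the record must share one ``.dat`` file
    (the layout ECG-ID and most PhysioNet databases use).
    """
    p = Path(path)
    hea = p if p.suffix == ".hea" else p.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"WFDB header not found: {hea}")
    name, n_sig, fs, n_samp, sigs = _parse_header(hea)
    if not 0 <= channel < n_sig:
        raise ValueError(f"channel {channel} out of range (record has {n_sig})")
    fnames = {s["fname"] for s in sigs}
    if len(fnames) != 1:
        raise FormatError(f"{hea}: multi-file records are not supported")
    fmts = {s["fmt"] for s in sigs}
    if len(fmts) != 1:
        raise FormatError(f"{hea}: mixed signal formats are not supported")
    dat = hea.parent / sigs[0]["fname"]
    if not dat.exists():
        raise FormatError(f"WFDB signal file not found: {dat}")
    digital = _decode_dat(dat.read_bytes(), sigs[0]["fmt"], n_sig)
    if n_samp:
        digital = digital[:n_samp]
    sig = sigs[channel]
    physical = (digital[:, channel] - sig["baseline"]) / sig["gain"]
    return EcgSignal(samples=physical, fs=fs, record_id=name)


def write_wfdb_record(
    signal: EcgSignal,
    path: str | PathLike,
    gain: float = 1000.0,
    units: str = "mV",
) -> None:
    """Write a single-signal WFDB record (format 16) for testing/export.

    Quantization step is ``1 / gain`` mV; values are clipped to the
    16-bit range.
    """
    p = Path(path)
    name = p.stem
    hea = p.with_suffix(".hea")
    dat_name = name + ".dat"
    digital = np.clip(np.round(signal.samples * gain), -32768, 32767).astype("<i2")
    fs = signal.fs
    fs_str = f"{fs:g}"
    hea.write_text(
        f"{name} 1 {fs_str} {digital.size}\n"
        f"{dat_name} 16 {gain:g}(0)/{units} 16 0 {int(digital[0])} 0 0 ECG\n"
    )
    (p.parent / dat_name).write_bytes(digital.tobytes())


def _numeric_rows(path: Path) -> tuple[list[list[float]], bool]:
    """Parse delimited numeric rows; returns rows and header-detected flag."""
    rows: list[list[float]] = []
    had_header = False
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.reader(fh), start=1):
            rec = [c.strip() for c in rec if c.strip() != ""]
            if not rec:
                continue
            try:
                rows.append([float(c) for c in rec])
            except ValueError:
                if lineno == 1 and not rows:
                    had_header = True  # single optional header line
                    continue
                raise FormatError(
                    f"{path}: non-numeric value on line {lineno}: {rec!r}"
                ) from None
    return rows, had_header


def read_delimited(
    path: str | PathLike, fs: float | None = None, record_id: str | None = None
) -> EcgSignal:
    """Read a one- or two-column delimited signal file.

    One column is voltage and requires an explicit ``fs``.  With two
    columns (time + voltage) and no explicit ``fs``, the rate is inferred
    from the median time spacing; spacing deviating from the median by
    more than 1% is rejected as non-uniform.
    """
    p = Path(path)
    rows, _ = _numeric_rows(p)
    if not rows:
        raise FormatError(f"{p}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths.pop() not in (1, 2):
        raise FormatError(f"{p}: expected 1 or 2 numeric columns on every row")
    arr = np.asarray(rows, dtype=np.float64)
    rid = record_id if record_id is not None else p.stem
    if arr.shape[1] == 1:
        if fs is None:
            raise ValueError("single-column file requires an explicit fs")
        return EcgSignal(samples=arr[:, 0], fs=fs, record_id=rid)
    voltage = arr[:, 1]
    if fs is not None:
        return EcgSignal(samples=voltage, fs=fs, record_id=rid)
    dt = np.diff(arr[:, 0])
    if np.any(dt <= 0):
        raise FormatError(f"{p}: time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise FormatError(f"{p}: non-uniform sampling (spacing deviates > 1% from median)")
    return EcgSignal(samples=voltage, fs=1.0 / med, record_id=rid)


def write_delimited(signal: EcgSignal, path: str | PathLike, time_column: bool = True) -> None:
    """Write the signal as CSV, ``time_s,voltage_mV`` (or voltage only)."""
    if time_column:
        df = pd.DataFrame({"time_s": signal.times, "voltage_mV": signal.samples})
    else:
        df = pd.DataFrame({"voltage_mV": signal.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def write_annotations(
    annotations: Sequence[FiducialAnnotation],
    path: str | PathLike,
    fs: float,
    record_id: str = "",
) -> None:
    """Write annotations as a delimited table, sorted order required.

    Columns: record_id, label, sample_index, time_s, amplitude_mV.
    Duplicate (label, index) pairs or unsorted input raise
    :class:`ValidationError`.
    """
    idx = [a.index for a in annotations]
    if any(b < a for a, b in zip(idx, idx[1:])):
        raise ValidationError("annotations must be sorted by sample index")
    keys = [(a.label, a.index) for a in annotations]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (label, index) annotation pairs")
    df = pd.DataFrame(
        {
            "record_id": [record_id] * len(annotations),
            "label": [a.label for a in annotations],
            "sample_index": [a.index for a in annotations],
            "time_s": [a.index / fs for a in annotations],
            "amplitude_mV": [a.amplitude for a in annotations],
        },
        columns=_ANNOTATION_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_annotations(path: str | PathLike) -> list[FiducialAnnotation]:
    """Read an annotation table written by :func:`write_annotations`."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = {"label", "sample_index", "amplitude_mV"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        label = str(row["label"])
        if label not in LABELS:
            raise ValidationError(f"{path}: unknown label {label!r}")
        out.append(
            FiducialAnnotation(
                index=int(row["sample_index"]),
                label=label,
                amplitude=float(row["amplitude_mV"]),
            )
        )
    out.sort()
    return out


def read_signal(path: str | PathLike, fs: float | None = None, channel: int = 0) -> EcgSignal:
    """Dispatch on extension: ``.hea``/``.dat`` → WFDB, else delimited."""
    p = Path(path)
    if p.suffix in (".hea", ".dat") or p.with_suffix(".hea").exists():
        return read_wfdb_record(p, channel=channel)
    return read_delimited(p, fs=fs)
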