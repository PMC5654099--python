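"""File-format plumbing: CSV readers/writers and a minimal WFDB reader.

All CSVs carry a one-line header; times are in seconds and sample indices
are 0-based.  The WFDB reader handles the common single/dual-channel
header+signal layout (formats 16 and 212) sufficient for PhysioNet-style
ECG records.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import FeatureMatrix
from .exceptions import ParameterError
from .hrv import HrvSignal, RRSeries
from .preprocess import EcgRecord, RPeakList
from .wavelet import EntropyFeatures

__all__ = [
    "read_ecg_csv", "write_ecg_csv", "read_wfdb", "write_peaks_csv",
    "read_rr_csv", "write_rr_csv", "read_hrv_csv", "write_hrv_csv",
    "write_features_csv", "read_features_csv",
]


def read_ecg_csv(path: str | Path, fs: float,
                 record_id: str | None = None) -> EcgRecord:
    """One-column CSV of samples (header ``sample``); fs supplied by caller."""
    df = pd.read_csv(path)
    if df.shape[1] < 1 or df.shape[0] == 0:
        raise ParameterError(f"{path}: no samples")
    col = df.columns[0]
    samples = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
    return EcgRecord(samples, fs, record_id or Path(path).stem)


def write_ecg_csv(record: EcgRecord, path: str | Path) -> None:
    pd.DataFrame({"sample": record.samples}).to_csv(path, index=False)


def read_wfdb(header_path: str | Path, channel: int = 0) -> EcgRecord:
    """Minimal WFDB header+signal reader (formats 16 and 212).

    Parses the ``.hea`` header for channel count, sampling rate, format,
    gain and baseline, reads the interleaved ``.dat`` samples and returns
    the selected channel in physical units.
    """
    header_path = Path(header_path)
    lines = [ln for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    record_name = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    if not 0 <= channel < n_sig:
        raise ParameterError(f"channel {channel} outside 0..{n_sig - 1}")
    sig_specs = []
    for ln in lines[1:1 + n_sig]:
        f = ln.split()
        fname = f[0]
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain = 200.0
        baseline = 0
        if len(f) > 2:
            g = f[2]
            if "(" in g:
                gain_s, rest = g.split("(", 1)
                baseline = int(rest.split(")")[0])
                gain = float(gain_s or 200.0)
            else:
                gain = float(g.split("/")[0] or 200.0)
        sig_specs.append((fname, int(fmt), gain, baseline))
    fname = sig_specs[channel][0]
    fmts = {s[1] for s in sig_specs}
    if len(fmts) != 1:
        raise ParameterError("mixed signal formats not supported")
    fmt = fmts.pop()
    dat_path = header_path.parent / fname
    raw = np.fromfile(dat_path, dtype=np.uint8)
    if fmt == 16:
        data = raw.view("<i2").astype(int).reshape(-1, n_sig)
    elif fmt == 212:
        raw = raw[: (raw.size // 3) * 3].reshape(-1, 3).astype(int)
        first = raw[:, 0] + ((raw[:, 1] & 0x0F) << 8)
        second = raw[:, 2] + ((raw[:, 1] & 0xF0) << 4)
        first[first > 2047] -= 4096
        second[second > 2047] -= 4096
        data = np.column_stack([first, second]).reshape(-1)[
            : (raw.shape[0] * 2 // n_sig) * n_sig].reshape(-1, n_sig)
    else:
        raise ParameterError(f"unsupported WFDB format {fmt}")
    _, _, gain, baseline = sig_specs[channel]
    physical = (data[:, channel] - baseline) / gain
    return EcgRecord(physical, fs, record_name)


def write_peaks_csv(peaks: RPeakList, path: str | Path) -> None:
    pd.DataFrame({
        "sample_index": peaks.indices,
        "time_s": peaks.indices / peaks.fs,
    }).to_csv(path, index=False)


def write_rr_csv(rr: RRSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": rr.times_s, "rr_s": rr.intervals_s})
    if rr.label is not None:
        df["label"] = rr.label
    df.to_csv(path, index=False)


def read_rr_csv(path: str | Path, record_id: str | None = None) -> RRSeries:
    df = pd.read_csv(path)
    for col in ("time_s", "rr_s"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    times = pd.to_numeric(df["time_s"], errors="raise").to_numpy(float)
    rr_s = pd.to_numeric(df["rr_s"], errors="raise").to_numpy(float)
    # millisecond inputs are auto-rescaled
    if rr_s.size and np.median(rr_s) > 10.0:
        rr_s = rr_s / 1000.0
        if np.median(np.diff(times)) > 10.0:
            times = times / 1000.0
    label = str(df["label"].iloc[0]) if "label" in df.columns else None
    return RRSeries(times, rr_s, record_id or Path(path).stem, label)


def write_hrv_csv(sig: HrvSignal, path: str | Path) -> None:
    t = np.arange(len(sig)) / sig.fs_hrv
    df = pd.DataFrame({"time_s": t, "rr_s": sig.values})
    if sig.label is not None:
        df["label"] = sig.label
    df.to_csv(path, index=False)


def read_hrv_csv(path: str | Path, fs_hrv: float,
                 record_id: str | None = None) -> HrvSignal:
    df = pd.read_csv(path)
    if "rr_s" not in df.columns:
        raise ParameterError(f"{path}: missing column 'rr_s'")
    label = str(df["label"].iloc[0]) if "label" in df.columns else None
    return HrvSignal(df["rr_s"].to_numpy(float), fs_hrv,
                     record_id or Path(path).stem, label)


def write_features_csv(features: list[EntropyFeatures],
                       path: str | Path) -> None:
    """Columns: record_id, label, alpha, H1..Hm."""
    if not features:
        raise ParameterError("no features to write")
    m = features[0].H.size
    rows = []
    for f in features:
        row = {"record_id": f.record_id, "label": f.label or "", "alpha":
               f.alpha}
        row.update({f"H{j}": f.H[j - 1] for j in range(1, m + 1)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features_csv(path: str | Path,
                      positive_label: str) -> FeatureMatrix:
    df = pd.read_csv(path)
    hcols = [c for c in df.columns if c.startswith("H") and c[1:].isdigit()]
    hcols.sort(key=lambda c: int(c[1:]))
    if not hcols:
        raise ParameterError(f"{path}: no H columns found")
    X = df[hcols].to_numpy(float)
    y = np.where(df["label"].astype(str) == positive_label, 1, -1)
    return FeatureMatrix(X, y, df["record_id"].astype(str).tolist(), hcols)
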