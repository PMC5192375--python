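"""Readers and writers for signals, annotations, detections and parameters.

Supported signal inputs are delimited text (a single column of samples
with the sampling frequency given separately, or two columns
``time_s,value`` from which the frequency is inferred) and WFDB records.
The WFDB support is a purpose-written minimal reader for the common
subset of the format: header files with one segment, signal formats 16
and 212 with gain/baseline conversion to physical units, and the standard
annotation file encoding.

Conventions: 0-based sample indices everywhere, times in seconds with six
decimal places, comma-separated output files with a mandatory header row.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DetectionResult, SignalRecord, TermaParams
from .evaluation import AnnotationSet

__all__ = [
    "read_signal",
    "read_annotations",
    "write_detections",
    "read_detections",
    "load_params",
    "save_params",
    "read_wfdb_signal",
    "read_wfdb_annotations",
]

DETECTION_COLUMNS = ["record", "peak_sample", "peak_time_s", "block_onset", "block_offset"]


class ConfigurationError(ValueError):
    """A missing or contradictory run configuration (e.g. unresolvable fs)."""


# ---------------------------------------------------------------------------
# Delimited text signals
# ---------------------------------------------------------------------------


def _read_table(path: Path) -> pd.DataFrame:
    """Read a CSV/TSV, tolerating an optional header row."""
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    first = pd.read_csv(path, sep=sep, header=None, nrows=1)
    try:
        first.astype(float)
        header = None
    except (ValueError, TypeError):
        header = 0
    return pd.read_csv(path, sep=sep, header=header)


def read_signal(
    path: str | Path,
    fmt: str = "auto",
    channel: int = 0,
    fs_override: float | None = None,
) -> SignalRecord:
    """Load a single-channel signal from CSV/TSV or a WFDB record.

    For single-column text files ``fs_override`` is required; for
    two-column ``time_s,value`` files the frequency is inferred from the
    median inter-sample interval.  For WFDB, ``path`` may point at the
    ``.hea`` file or at the header-less record name; ``channel`` selects
    the signal (0-based) and gain/baseline from the header are applied so
    samples come back in physical units.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "wfdb" if path.suffix.lower() == ".hea" else "csv"
    if fmt == "wfdb":
        return read_wfdb_signal(path, channel=channel)
    if fmt != "csv":
        raise ConfigurationError(f"unknown signal format {fmt!r} (expected csv or wfdb)")

    df = _read_table(path)
    if df.shape[1] == 1:
        if fs_override is None:
            raise ConfigurationError(
                f"{path}: single-column signal file needs an explicit sampling frequency"
            )
        samples = df.iloc[:, 0].to_numpy(dtype=float)
        fs = float(fs_override)
    elif df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        samples = df.iloc[:, 1].to_numpy(dtype=float)
        if fs_override is not None:
            fs = float(fs_override)
        else:
            dt = np.median(np.diff(t))
            if not (dt > 0):
                raise ConfigurationError(f"{path}: time column is not increasing")
            fs = 1.0 / dt
    else:
        raise ConfigurationError(f"{path}: empty signal file")

    n_bad = int(np.count_nonzero(~np.isfinite(samples)))
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite sample(s) in signal")
    return SignalRecord(samples=samples, fs=fs, label=path.stem)


# ---------------------------------------------------------------------------
# Minimal WFDB reader (header + formats 16/212, standard annotations)
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_name = rec_fields[0].split("/")[0]
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    nsamp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = f[2] if len(f) > 2 else "200"
        units = ""
        if "/" in gain_field:
            gain_field, units = gain_field.split("/", 1)
        if "(" in gain_field:
            gain_s, base_s = gain_field[:-1].split("(")
            gain, baseline = float(gain_s), int(base_s)
        else:
            gain = float(gain_field)
            adczero = int(f[4]) if len(f) > 4 else 0
            baseline = adczero
        if gain == 0:
            gain = 200.0
        signals.append(
            {"filename": f[0], "fmt": fmt, "gain": gain, "baseline": baseline,
             "units": units}
        )
    return record_name, nsig, fs, nsamp, signals


def _decode_212(data: bytes, nsig: int) -> np.ndarray:
    b = np.frombuffer(data, dtype=np.uint8)
    b = b[: 3 * (b.size // 3)].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    flat = np.empty(2 * b.shape[0], dtype=np.int32)
    flat[0::2], flat[1::2] = first, second
    return flat


def read_wfdb_signal(path: str | Path, channel: int = 0) -> SignalRecord:
    """Read one channel of a WFDB record (.hea plus .dat, format 16 or 212)."""
    path = Path(path)
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    record_name, nsig, fs, nsamp, signals = _parse_header(hea_path)
    if not (0 <= channel < nsig):
        raise ConfigurationError(
            f"channel {channel} out of range for {nsig}-channel record {record_name}"
        )
    sig = signals[channel]
    dat_path = hea_path.parent / sig["filename"]
    data = dat_path.read_bytes()
    fmt = sig["fmt"]
    if fmt == "16":
        flat = np.frombuffer(data, dtype="<i2").astype(np.int32)
    elif fmt == "212":
        flat = _decode_212(data, nsig)
    else:
        raise ConfigurationError(f"unsupported WFDB signal format {fmt!r}")
    flat = flat[: nsig * (flat.size // nsig)]
    adc = flat.reshape(-1, nsig)[:, channel]
    if nsamp:
        adc = adc[:nsamp]
    physical = (adc - sig["baseline"]) / sig["gain"]
    return SignalRecord(samples=physical, fs=fs, label=record_name)


#: Annotation code -> display symbol for the standard annotation set
#: (beat codes 1-13 and the common non-beat codes).
_ANN_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_BEAT_CODES = frozenset(range(1, 14)) | {25, 34, 35, 38, 41}


def read_wfdb_annotations(
    path: str | Path,
    fs: float,
    symbols: str | None = None,
    label: str = "",
) -> AnnotationSet:
    """Read a WFDB annotation file into sample indices.

    ``symbols`` restricts the returned events to the given display
    symbols (e.g. ``"NLRV"``); by default all beat-type annotations are
    returned.
    """
    data = Path(path).read_bytes()
    events: list[int] = []
    time = 0
    i = 0
    while i + 1 < len(data):
        a, b = data[i], data[i + 1]
        i += 2
        code = b >> 2
        interval = ((b & 0x03) << 8) | a
        if code == 0 and interval == 0:  # EOF
            break
        if code == 59:  # SKIP: 4-byte interval follows, high word first
            if interval == 0 and i + 3 < len(data):
                high = struct.unpack("<H", data[i : i + 2])[0]
                low = struct.unpack("<H", data[i + 2 : i + 4])[0]
                time += struct.unpack("<i", struct.pack("<I", (high << 16) | low))[0]
                i += 4
            continue
        if code in (60, 61):  # NUM / SUB: modifier only
            continue
        if code == 62:  # AUX: interval bytes of text, padded to even
            i += interval + (interval & 1)
            continue
        time += interval
        sym = _ANN_SYMBOLS.get(code)
        if symbols is not None:
            if sym in symbols:
                events.append(time)
        elif code in _BEAT_CODES:
            events.append(time)
    return AnnotationSet(events=np.asarray(sorted(set(events)), dtype=int), fs=fs,
                         label=label or Path(path).stem)


# ---------------------------------------------------------------------------
# Annotations (text), detections, parameters
# ---------------------------------------------------------------------------


def read_annotations(
    path: str | Path,
    fs: float,
    fmt: str = "auto",
    symbols: str | None = None,
) -> AnnotationSet:
    """Reference event indices from a one-column CSV or a WFDB annotation file."""
    path = Path(path)
    if fmt == "auto":
        fmt = "csv" if path.suffix.lower() in (".csv", ".tsv", ".txt", "") else "wfdb"
    if fmt == "wfdb":
        return read_wfdb_annotations(path, fs=fs, symbols=symbols)
    df = _read_table(path)
    events = np.sort(df.iloc[:, 0].to_numpy(dtype=int))
    return AnnotationSet(events=events, fs=fs, label=path.stem)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    pd.DataFrame({"sample": annotations.events}).to_csv(path, index=False)


def write_detections(result: DetectionResult, path: str | Path) -> None:
    """Write peaks and their blocks as CSV; empty results produce a header-only file."""
    fs = result.record.fs
    rows = []
    for peak, (onset, offset) in zip(result.peaks, result.blocks.blocks):
        rows.append(
            {
                "record": result.record.label,
                "peak_sample": int(peak),
                "peak_time_s": f"{peak / fs:.6f}",
                "block_onset": onset,
                "block_offset": offset,
            }
        )
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections(path: str | Path) -> np.ndarray:
    """Peak sample indices from a detections CSV (sorted)."""
    df = pd.read_csv(path)
    col = "peak_sample" if "peak_sample" in df.columns else df.columns[0]
    return np.sort(df[col].to_numpy(dtype=int))


def load_params(path: str | Path) -> TermaParams:
    """Load detector parameters from JSON or YAML.

    Keys: ``F1_hz, F2_hz, W1_ms, W2_ms, beta`` with beta as a fraction.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    try:
        return TermaParams(
            F1=float(data["F1_hz"]), F2=float(data["F2_hz"]),
            W1_ms=float(data["W1_ms"]), W2_ms=float(data["W2_ms"]),
            beta=float(data["beta"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing parameter key {exc}") from exc


def params_to_dict(params: TermaParams) -> dict:
    return {
        "F1_hz": params.F1, "F2_hz": params.F2,
        "W1_ms": params.W1_ms, "W2_ms": params.W2_ms, "beta": params.beta,
    }


def save_params(params: TermaParams, path: str | Path) -> None:
    path = Path(path)
    data = params_to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_grid(path: str | Path):
    """Grid configuration from YAML with keys f1_hz, f2_hz, w1_ms, w2_ms, beta."""
    from .optimization import GridSpec

    data = yaml.safe_load(Path(path).read_text())
    try:
        return GridSpec(
            f1_values=tuple(data["f1_hz"]),
            f2_values=tuple(data["f2_hz"]),
            w1_values=tuple(data["w1_ms"]),
            w2_values=tuple(data["w2_ms"]),
            beta_values=tuple(data["beta"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing grid key {exc}") from exc
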