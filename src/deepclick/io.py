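"""CSV/WAV readers and writers for every pipeline table.

Every CSV written here carries provenance comment lines (``# key=value``)
recording at minimum the seed and config hash that produced it; readers
return the table and that metadata.  Time columns are seconds from day start;
dates are ISO-8601; the single timezone is UTC.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "read_detection_csv",
    "write_calls_csv",
    "read_calls_csv",
    "write_sequences_csv",
    "write_wav",
    "read_wav",
]

CALLS_COLUMNS = ["day_id", "present", "n_sequences", "n_candidates"]
SEQUENCE_COLUMNS = ["day_id", "start_s", "n_intervals", "rounded_idi_s", "mean_ici_s"]
DETECTION_COLUMNS = ["day_id", "time_s"]


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    return hashlib.sha256(repr(sorted(str(obj).split())).encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV with ``# key=value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_table(path, required: list[str] | None = None) -> tuple[pd.DataFrame, dict]:
    """Read a provenance-carrying CSV; error names any missing required column."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    for col in required or []:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df, meta


def read_detection_csv(path) -> pd.DataFrame:
    """Detection-time table (day_id, time_s); malformed rows error with line number."""
    df, _ = read_table(path, required=DETECTION_COLUMNS)
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.flatnonzero(times.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering (comment lines precede but
        # pandas line refs are of limited use; report the table row instead)
        raise ValueError(f"{path}: malformed time_s in table row {bad[0] + 1}")
    df["time_s"] = times
    return df


def write_calls_csv(calls, path, meta: dict | None = None) -> None:
    """Daily-call table: one row per day with presence and counts."""
    rows = [
        {
            "day_id": c.day_id,
            "present": bool(c.present),
            "n_sequences": len(c.sequences),
            "n_candidates": c.n_candidates,
        }
        for c in calls
    ]
    write_table(pd.DataFrame(rows, columns=CALLS_COLUMNS), path, meta)


def read_calls_csv(path) -> tuple[pd.DataFrame, dict]:
    df, meta = read_table(path, required=CALLS_COLUMNS)
    df["present"] = df["present"].astype(bool)
    return df, meta


def write_sequences_csv(calls, path, meta: dict | None = None) -> None:
    """Per-sequence table across days (start, run length, rounded IDI, mean ICI)."""
    rows = []
    for c in calls:
        for s in c.sequences:
            rows.append(
                {
                    "day_id": c.day_id,
                    "start_s": s.start_s,
                    "n_intervals": s.n_intervals,
                    "rounded_idi_s": s.rounded_idi,
                    "mean_ici_s": s.mean_ici,
                }
            )
    write_table(pd.DataFrame(rows, columns=SEQUENCE_COLUMNS), path, meta)


def write_wav(path, waveform: np.ndarray, fs: float = 16000.0) -> None:
    """Write mono float32 WAV."""
    wavfile.write(Path(path), int(fs), np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    fs, data = wavfile.read(Path(path))
    return np.asarray(data, dtype=float), float(fs)
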