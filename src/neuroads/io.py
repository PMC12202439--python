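"""File formats: EDF, the Emotiv-style CSV sample dialect, and tidy CSVs.

The EDF writer/reader implements the plain EDF layout (256-byte header plus
one 256-byte block per signal; 16-bit little-endian data records) with
1-second records: 14 EEG signals in microvolts plus one marker signal.  The
recording is zero-padded to a whole number of records; the true sample count
is stored in the reserved header field so a round trip through this module
restores the exact length, while other EDF readers simply see the padded
record grid.

The Emotiv-style CSV dialect has one row per sample with the 14 channel
columns followed by a MARKER column of 0/1, matching the layout produced by
the Emotiv plugin for stimulus-presentation software.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from neuroads.types import ParameterError, Recording, StructuralError

__all__ = [
    "write_edf",
    "read_edf",
    "write_emotiv_csv",
    "read_emotiv_csv",
    "write_ratings_csv",
    "read_ratings_csv",
    "write_sessions_csv",
    "read_sessions_csv",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ParameterError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path, recording: Recording) -> None:
    """Write a recording as EDF: 14 EEG signals (uV) + 1 marker signal."""
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    signals = np.vstack([recording.data, recording.marker.astype(float)])
    labels = list(recording.channel_labels) + ["MARKER"]
    dims = ["uV"] * len(recording.channel_labels) + [""]
    ns, n = signals.shape
    n_rec = math.ceil(n / fs)
    padded = np.zeros((ns, n_rec * fs))
    padded[:, :n] = signals

    phys_min, phys_max, gains = [], [], []
    for k in range(ns):
        pm = float(np.ceil(np.max(np.abs(padded[k])))) + 1.0
        phys_min.append(-pm)
        phys_max.append(pm)
        gains.append((_DIG_MAX - _DIG_MIN) / (2 * pm))

    header = b""
    header += _fixed("0", 8)
    header += _fixed(recording.subject_id, 80)
    header += _fixed(f"Startdate 01-JAN-2000 {recording.subject_id}", 80)
    header += _fixed("01.01.00", 8)
    header += _fixed("00.00.00", 8)
    header += _fixed(256 * (ns + 1), 8)
    header += _fixed(f"NSAMP={n}", 44)  # true length; EDF reserves this field
    header += _fixed(n_rec, 8)
    header += _fixed(1, 8)
    header += _fixed(ns, 4)
    for field, width in ((labels, 16), (["" for _ in range(ns)], 80), (dims, 8),
                         ([f"{v:g}" for v in phys_min], 8),
                         ([f"{v:g}" for v in phys_max], 8),
                         ([str(_DIG_MIN) for _ in range(ns)], 8),
                         ([str(_DIG_MAX) for _ in range(ns)], 8),
                         (["" for _ in range(ns)], 80),
                         ([str(fs) for _ in range(ns)], 8),
                         (["" for _ in range(ns)], 32)):
        for v in field:
            header += _fixed(v, width)

    digital = np.empty_like(padded, dtype=np.int16)
    for k in range(ns):
        digital[k] = np.round((padded[k] - phys_min[k]) * gains[k] + _DIG_MIN).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = digital[:, r * fs:(r + 1) * fs]
            fh.write(chunk.astype("<i2").tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file written by :func:`write_edf` back into a Recording."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        subject_id = head[8:88].decode("ascii").strip()
        reserved = head[184:228].decode("ascii").strip()
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        ns = int(head[252:256])
        sig = fh.read(256 * ns)

        def field(offset, width):
            start = offset * ns
            return [sig[start + i * width:start + (i + 1) * width].decode("ascii").strip()
                    for i in range(ns)]

        labels = field(0, 16)
        pos = ns * (16 + 80 + 8)
        phys_min = [float(sig[pos + i * 8:pos + (i + 1) * 8]) for i in range(ns)]
        pos += ns * 8
        phys_max = [float(sig[pos + i * 8:pos + (i + 1) * 8]) for i in range(ns)]
        pos += ns * 8
        dig_min = [int(sig[pos + i * 8:pos + (i + 1) * 8]) for i in range(ns)]
        pos += ns * 8
        dig_max = [int(sig[pos + i * 8:pos + (i + 1) * 8]) for i in range(ns)]
        pos += ns * 8 + ns * 80
        spr = [int(sig[pos + i * 8:pos + (i + 1) * 8]) for i in range(ns)]
        raw = np.frombuffer(fh.read(), dtype="<i2")

    if len(set(spr)) != 1:
        raise StructuralError("mixed samples-per-record EDF not supported")
    fs = spr[0] / rec_dur
    per_rec = sum(spr)
    raw = raw[: n_rec * per_rec].reshape(n_rec, ns, spr[0])
    data = np.concatenate([raw[:, k, :].reshape(-1)[None, :] for k in range(ns)], axis=0).astype(float)
    for k in range(ns):
        gain = (dig_max[k] - dig_min[k]) / (phys_max[k] - phys_min[k])
        data[k] = (data[k] - dig_min[k]) / gain + phys_min[k]

    n = n_rec * spr[0]
    if reserved.startswith("NSAMP="):
        n = int(reserved.split("=", 1)[1])
    if labels[-1] != "MARKER":
        raise StructuralError("last EDF signal is expected to be the MARKER track")
    marker = np.round(data[-1, :n]).astype(int)
    return Recording(
        subject_id=subject_id, sampling_rate=fs, data=data[:-1, :n],
        marker=marker, channel_labels=tuple(labels[:-1]),
    )


# -- Emotiv-style CSV ------------------------------------------------------


def write_emotiv_csv(path, recording: Recording) -> None:
    """One row per sample: 14 channel columns then a MARKER column of 0/1."""
    df = pd.DataFrame(recording.data.T, columns=list(recording.channel_labels))
    df["MARKER"] = recording.marker.astype(int)
    df.to_csv(path, index=False, float_format="%.17g")  # exact float64 round-trip


def read_emotiv_csv(path, sampling_rate: float, subject_id: str = "unknown",
                    stimulus_order: Optional[Sequence[str]] = None) -> Recording:
    """Read the sample-dialect CSV back (the dialect stores no metadata)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "MARKER" not in df.columns:
        raise StructuralError(f"{path}: no MARKER column")
    channels = [c for c in df.columns if c != "MARKER"]
    return Recording(
        subject_id=subject_id, sampling_rate=sampling_rate,
        data=df[channels].to_numpy().T, marker=df["MARKER"].to_numpy().astype(int),
        channel_labels=tuple(channels),
        stimulus_order=tuple(stimulus_order) if stimulus_order else None,
    )


# -- tidy CSVs -------------------------------------------------------------


def write_ratings_csv(path, ratings: pd.DataFrame) -> None:
    ratings.to_csv(path, index=False)


def read_ratings_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ratings file not found: {path}")
    df = pd.read_csv(path)
    required = {"subject_id", "ad_id", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise StructuralError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_sessions_csv(path, recordings: Sequence[Recording]) -> None:
    """Presentation order per subject (needed to match marker pairs to ads)."""
    rows = [dict(subject_id=r.subject_id, position=i, ad_id=ad)
            for r in recordings for i, ad in enumerate(r.stimulus_order or ())]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sessions_csv(path) -> dict[str, tuple[str, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sessions file not found: {path}")
    df = pd.read_csv(path).sort_values(["subject_id", "position"])
    return {s: tuple(g["ad_id"]) for s, g in df.groupby("subject_id", sort=False)}


def write_manifest(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
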