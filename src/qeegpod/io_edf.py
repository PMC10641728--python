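"""EDF import/export for synthetic and clinical recordings.

Writing uses a minimal, self-contained EDF encoder (16-bit samples,
1-second data records, physical range set from the data with 5%
headroom).  Reading goes through :mod:`mne`, the de-facto standard EEG
reader, which also makes the write→read roundtrip an independent check
of the encoder.
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EEGRecording

_RECORD_S = 1.0  # EDF data-record duration (s)
_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: EEGRecording, path: "str | Path") -> Path:
    """Write a recording to EDF (µV physical units).

    The physical range of each channel is its data min/max widened by
    5% so quantization headroom exists; samples are encoded as 16-bit
    integers in 1-second records.  A trailing partial second is
    dropped.  Non-finite samples are rejected.
    """
    path = Path(path)
    x = recording.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("recording contains non-finite samples; cannot encode EDF")
    fs = recording.fs
    spr = int(round(fs * _RECORD_S))
    if abs(spr - fs * _RECORD_S) > 1e-9:
        raise ValueError("sampling rate must yield an integer number of samples per 1 s record")
    n_records = x.shape[1] // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    n_ch = recording.n_channels

    phys_min, phys_max = [], []
    for row in x:
        lo, hi = float(row.min()), float(row.max())
        span = hi - lo
        pad = 0.05 * span if span > 0 else 1.0
        phys_min.append(lo - pad)
        phys_max.append(hi + pad)

    start = recording.start_time
    header = b"".join(
        [
            _field("0", 8),
            _field(f"X X X {recording.subject_id or 'X'}", 80),
            _field(f"Startdate {start:%d-%b-%Y} X X X", 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field(f"{_RECORD_S:g}", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lb, 16) for lb in recording.channel_labels),
            b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{m:.7g}"[:8], 8) for m in phys_min),
            b"".join(_field(f"{m:.7g}"[:8], 8) for m in phys_max),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("HP:0.1Hz LP:40Hz", 80) for _ in range(n_ch)),
            b"".join(_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    # physical -> digital, per channel
    digital = np.empty((n_ch, n_records * spr), dtype="<i2")
    for ch in range(n_ch):
        lo, hi = phys_min[ch], phys_max[ch]
        gain = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        d = np.rint((x[ch, : n_records * spr] - lo) * gain + _DIG_MIN)
        digital[ch] = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for rec_i in range(n_records):
            sl = slice(rec_i * spr, (rec_i + 1) * spr)
            for ch in range(n_ch):
                fh.write(digital[ch, sl].tobytes())
    return path


def read_edf(path: "str | Path") -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (µV).

    Channels with mixed sampling rates are resampled to a common rate
    by the mne reader (with a logged warning from mne itself).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise ValueError(f"could not parse {path} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    meas_date = raw.info.get("meas_date")
    kwargs = {}
    if meas_date is not None:
        kwargs["start_time"] = meas_date
    return EEGRecording(
        samples=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=path.stem,
        **kwargs,
    )


def write_cohort(
    recordings: "list[EEGRecording]", out_dir: "str | Path"
) -> pd.DataFrame:
    """Write one EDF per subject plus a ``manifest.csv``.

    The manifest maps subject_id → group_label and file name; it is
    what ``analyze`` mode uses to restore group membership.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id or 'subject'}.edf"
        write_edf(rec, out_dir / fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group_label": rec.group_label,
                "file": fname,
                "fs_hz": rec.fs,
                "duration_s": rec.duration_s,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_cohort(in_dir: "str | Path") -> "list[EEGRecording]":
    """Read every recording listed in a cohort manifest (or all EDFs)."""
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.csv"
    recs = []
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path, keep_default_na=False)
        for _, row in manifest.iterrows():
            rec = read_edf(in_dir / row["file"])
            recs.append(
                EEGRecording(
                    samples=rec.samples,
                    fs=rec.fs,
                    channel_labels=rec.channel_labels,
                    start_time=rec.start_time,
                    subject_id=str(row["subject_id"]),
                    group_label=str(row["group_label"]),
                )
            )
    else:
        for path in sorted(in_dir.glob("*.edf")):
            recs.append(read_edf(path))
    if not recs:
        raise FileNotFoundError(f"no EDF recordings found under {in_dir}")
    return recs
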