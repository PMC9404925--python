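"""Reading, writing and filtering of paired PPG/ABP signal records.

A record holds one subject's synchronized photoplethysmogram (arbitrary
units) and arterial blood pressure (mmHg) sampled at a common rate,
125 Hz for the clinical recordings this pipeline targets.

On-disk format: plain text, comma-delimited, two columns per row
``ppg,abp``, one sample per row, with an optional single header line
``# fs=<Hz> id=<string>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DEFAULT_FS = 125.0
#: records shorter than 8 minutes are excluded from the study population
DEFAULT_MIN_DURATION_S = 480.0
#: records whose ABP ever exceeds 200 mmHg are excluded
DEFAULT_MAX_ABP = 200.0


class RecordFormatError(ValueError):
    """Raised when a record file does not conform to the on-disk format."""


@dataclass
class SignalRecord:
    """One subject's synchronized PPG and ABP series at sampling rate ``fs``."""

    record_id: str
    fs: float
    ppg: np.ndarray
    abp: np.ndarray

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=np.float64)
        self.abp = np.asarray(self.abp, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.ppg.ndim != 1 or self.abp.ndim != 1:
            raise ValueError("ppg and abp must be one-dimensional")
        if len(self.ppg) != len(self.abp):
            raise ValueError(
                f"channel length mismatch: ppg has {len(self.ppg)} samples, "
                f"abp has {len(self.abp)}"
            )
        if len(self.ppg) == 0:
            raise ValueError("record must contain at least one sample")
        if not (np.all(np.isfinite(self.ppg)) and np.all(np.isfinite(self.abp))):
            raise ValueError("record contains non-finite samples")

    def __len__(self) -> int:
        return len(self.ppg)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (number of samples over ``fs``)."""
        return len(self.ppg) / self.fs


_HEADER_RE = re.compile(r"^#\s*fs=(?P<fs>[0-9.eE+-]+)(?:\s+id=(?P<id>\S+))?\s*$")


def read_record(path: str | Path, fs: float = DEFAULT_FS) -> SignalRecord:
    """Read a two-column ``ppg,abp`` record file.

    An optional first line ``# fs=<Hz> id=<string>`` overrides ``fs`` and
    supplies the record id; otherwise the id is the file stem.

    Raises
    ------
    RecordFormatError
        On an empty file, malformed row, or non-numeric sample, naming the
        offending line.
    """
    path = Path(path)
    record_id = path.stem
    ppg: list[float] = []
    abp: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _HEADER_RE.match(line)
                if m is None:
                    raise RecordFormatError(f"{path}:{lineno}: malformed header line {line!r}")
                fs = float(m.group("fs"))
                if m.group("id"):
                    record_id = m.group("id")
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise RecordFormatError(
                    f"{path}:{lineno}: expected two comma-separated values, got {line!r}"
                )
            try:
                ppg.append(float(parts[0]))
                abp.append(float(parts[1]))
            except ValueError as exc:
                raise RecordFormatError(f"{path}:{lineno}: non-numeric sample in {line!r}") from exc
    if not ppg:
        raise RecordFormatError(f"{path}: file contains no samples")
    return SignalRecord(record_id=record_id, fs=fs, ppg=np.array(ppg), abp=np.array(abp))


def write_record(record: SignalRecord, path: str | Path) -> None:
    """Write ``record`` so that :func:`read_record` round-trips it bit-identically."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={record.fs!r} id={record.record_id}\n")
        for p, a in zip(record.ppg, record.abp):
            fh.write(f"{float(p)!r},{float(a)!r}\n")


def write_signal(signal: Sequence[float], path: str | Path, fs: float = DEFAULT_FS,
                 channel: str = "abp_rec") -> None:
    """Write a single-channel signal (e.g. a stitched reconstruction), one sample per row."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={fs!r} channel={channel}\n")
        for v in np.asarray(signal, dtype=np.float64):
            fh.write(f"{float(v)!r}\n")


def filter_records(
    records: Iterable[SignalRecord],
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    max_abp: float = DEFAULT_MAX_ABP,
) -> list[SignalRecord]:
    """Apply the study's record-inclusion criteria.

    A record is kept when its duration is at least ``min_duration_s`` (records
    strictly shorter than 8 min are removed) and its ABP never rises above
    ``max_abp`` (a maximum of exactly 200 mmHg is kept; above 200 is removed).
    Order is preserved and the operation is idempotent.
    """
    if min_duration_s <= 0:
        raise ValueError("min_duration_s must be positive")
    return [
        r for r in records
        if r.duration_s >= min_duration_s and float(np.max(r.abp)) <= max_abp
    ]
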