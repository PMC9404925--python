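"""Preprocessing: detrending, ABP scaling, derivatives, windowing and the
chronological train/test split.

The model consumes fixed-length windows (default 1024 samples = 8.192 s at
125 Hz) cut with 75% overlap.  The PPG is detrended by removing its ordinary
least-squares line over the whole record; the ABP is divided by 200 so that
targets lie in [0, 1], compatible with the model's tanh output.  For the
three-channel input mode the PPG's first and second discrete derivatives
(VPG, APG — "velocity" and "acceleration" PPG) are computed on the full
record before segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .records import SignalRecord

DEFAULT_WINDOW = 1024
DEFAULT_OVERLAP = 0.75
DEFAULT_ABP_SCALE = 200.0
DEFAULT_TRAIN_FRAC = 0.8


class InputMode(str, Enum):
    PPG_ONLY = "PPG_ONLY"
    PPG_VPG_APG = "PPG_VPG_APG"


@dataclass
class SegmentSet:
    """Windowed, channel-stacked view of a record plus stitching bookkeeping.

    ``segments`` has shape (n_segments, window_len, n_channels); ``starts``
    holds each window's start sample in the source record and must be
    strictly increasing with constant spacing ``stride``.
    """

    segments: np.ndarray
    starts: np.ndarray
    window_len: int
    stride: int
    channel_names: list[str]
    abp_scale: float = DEFAULT_ABP_SCALE

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (n_segments, window_len, n_channels)")
        if self.segments.shape[0] != len(self.starts):
            raise ValueError("starts length must equal number of segments")
        if self.segments.shape[1] != self.window_len:
            raise ValueError("segment length does not match window_len")
        if len(self.starts) > 1:
            gaps = np.diff(self.starts)
            if not np.all(gaps == self.stride) or self.stride <= 0:
                raise ValueError("starts must increase with constant spacing == stride")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_channels(self) -> int:
        return self.segments.shape[2]


def detrend_linear(signal: Sequence[float]) -> np.ndarray:
    """Remove the ordinary least-squares line a·t + b fitted over sample index t.

    Exactly annihilates affine signals and is idempotent up to rounding.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("detrend_linear requires a 1-D signal of length >= 2")
    t = np.arange(len(x), dtype=np.float64)
    a, b = np.polyfit(t, x, 1)
    return x - (a * t + b)


def scale_abp(abp: Sequence[float], divisor: float = DEFAULT_ABP_SCALE) -> np.ndarray:
    """Divide ABP (mmHg) by ``divisor`` so that 0–200 mmHg maps to [0, 1]."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return np.asarray(abp, dtype=np.float64) / divisor


def derivative(signal: Sequence[float]) -> np.ndarray:
    """Discrete derivative: forward difference at the first sample, central
    difference (X(i+1) − X(i−1))/2 in the interior, backward difference at the
    last sample.  Output length equals input length."""
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("derivative requires a 1-D signal of length >= 2")
    out = np.empty_like(x)
    out[0] = x[1] - x[0]
    out[-1] = x[-1] - x[-2]
    if len(x) > 2:
        out[1:-1] = (x[2:] - x[:-2]) / 2.0
    return out


def segment(
    record_channels: Sequence[Sequence[float]],
    window_len: int = DEFAULT_WINDOW,
    overlap_frac: float = DEFAULT_OVERLAP,
    channel_names: list[str] | None = None,
    abp_scale: float = DEFAULT_ABP_SCALE,
) -> SegmentSet:
    """Cut equal-length channels into overlapping windows.

    ``stride = window_len * (1 - overlap_frac)`` must be a positive integer;
    a trailing stretch shorter than one window is dropped.  Segment ``k``
    covers samples ``[k*stride, k*stride + window_len)``.
    """
    channels = [np.asarray(c, dtype=np.float64) for c in record_channels]
    if not channels:
        raise ValueError("at least one channel required")
    L = len(channels[0])
    if any(len(c) != L for c in channels):
        raise ValueError("all channels must have equal length")
    if not (0.0 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must lie in [0, 1)")
    stride_f = window_len * (1.0 - overlap_frac)
    stride = int(round(stride_f))
    if stride <= 0 or abs(stride - stride_f) > 1e-9:
        raise ValueError(
            f"stride window_len*(1-overlap_frac) = {stride_f} must be a positive integer"
        )
    if L < window_len:
        raise ValueError(f"record length {L} shorter than one window ({window_len})")
    n_segments = (L - window_len) // stride + 1
    starts = np.arange(n_segments, dtype=np.int64) * stride
    data = np.empty((n_segments, window_len, len(channels)))
    for j, c in enumerate(channels):
        for k, s in enumerate(starts):
            data[k, :, j] = c[s:s + window_len]
    names = channel_names or [f"ch{j}" for j in range(len(channels))]
    return SegmentSet(segments=data, starts=starts, window_len=window_len,
                      stride=stride, channel_names=list(names), abp_scale=abp_scale)


def split_train_test(
    segset: SegmentSet, train_frac: float = DEFAULT_TRAIN_FRAC
) -> tuple[SegmentSet, SegmentSet]:
    """Chronological split: first ``floor(n*train_frac)`` segments train, rest test."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    n = segset.n_segments
    n_train = int(np.floor(n * train_frac))
    if n_train == 0 or n_train == n:
        raise ValueError(f"split of {n} segments at {train_frac} leaves one side empty")

    def _sub(lo: int, hi: int) -> SegmentSet:
        return SegmentSet(
            segments=segset.segments[lo:hi],
            starts=segset.starts[lo:hi],
            window_len=segset.window_len,
            stride=segset.stride,
            channel_names=list(segset.channel_names),
            abp_scale=segset.abp_scale,
        )

    return _sub(0, n_train), _sub(n_train, n)


def build_inputs(
    record: SignalRecord,
    mode: InputMode | str = InputMode.PPG_ONLY,
    window_len: int = DEFAULT_WINDOW,
    overlap_frac: float = DEFAULT_OVERLAP,
    abp_scale: float = DEFAULT_ABP_SCALE,
    zscore_ppg: bool = False,
) -> tuple[SegmentSet, SegmentSet]:
    """Produce aligned (input, target) segment sets for one record.

    The PPG is detrended first; in three-channel mode VPG and APG are
    derived from the detrended PPG on the full record, before segmentation.
    Targets are the ABP divided by ``abp_scale``, windowed with the same
    starts as the inputs.  ``zscore_ppg`` optionally standardizes each input
    channel over the record (off by default; amplitudes are passed raw).
    """
    mode = InputMode(mode)
    ppg = detrend_linear(record.ppg)
    if mode is InputMode.PPG_ONLY:
        chans = [ppg]
        names = ["PPG"]
    else:
        vpg = derivative(ppg)
        apg = derivative(vpg)
        chans = [ppg, vpg, apg]
        names = ["PPG", "VPG", "APG"]
    if zscore_ppg:
        chans = [(c - c.mean()) / (c.std() if c.std() > 0 else 1.0) for c in chans]
    inputs = segment(chans, window_len, overlap_frac, channel_names=names, abp_scale=abp_scale)
    targets = segment([scale_abp(record.abp, abp_scale)], window_len, overlap_frac,
                      channel_names=["ABP_scaled"], abp_scale=abp_scale)
    return inputs, targets
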