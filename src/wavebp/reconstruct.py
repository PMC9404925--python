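"""Amplitude restoration and overlap-discard stitching of predicted windows.

The model outputs scaled ABP windows with 75% overlap.  Stitching keeps, at
every junction, the leading ``stride`` samples of the earlier window and the
whole of the final window, so each output sample comes from exactly one
window and output sample ``t`` aligns with source sample ``t`` of the
covered range.  Restoring amplitude multiplies by the scaling divisor
(default 200) to return to mmHg.
"""

from __future__ import annotations

import numpy as np

from .preprocess import SegmentSet, DEFAULT_ABP_SCALE


def restore_amplitude(values, divisor: float = DEFAULT_ABP_SCALE) -> np.ndarray:
    """Element-wise multiplication by ``divisor``; inverse of ABP scaling."""
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    return np.asarray(values, dtype=np.float64) * divisor


def stitch(segset: SegmentSet, channel: int = 0) -> np.ndarray:
    """Stitch overlapped windows into one continuous signal.

    Iteratively the running signal drops its trailing ``window_len - stride``
    samples (the overlapped 75%) and the next full window is appended.  The
    result has length ``(n_segments - 1) * stride + window_len`` and equals
    the source signal on the covered range when applied to ground-truth
    windows.
    """
    if segset.n_segments < 1:
        raise ValueError("at least one segment required")
    segs = segset.segments[:, :, channel]
    if len(segset.starts) > 1:
        gaps = np.diff(segset.starts)
        if not np.all(gaps == segset.stride):
            raise ValueError("non-constant stride between segment starts")
    out = segs[0]
    for k in range(1, segset.n_segments):
        out = np.concatenate([out[: len(out) - (segset.window_len - segset.stride)], segs[k]])
    return out
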