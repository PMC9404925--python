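"""Waveform-similarity evaluation between a reference and a reconstructed ABP.

Five measures: RMSE, Pearson's r, normalized dynamic-time-warping distance,
and the mean absolute error of correspondence-matched systolic (SBP) and
diastolic (DBP) feature points.  Feature points are extracted by a
prominence-based delineator; a reference feature is matched to the nearest
reconstructed feature of the same kind whose sample position differs by
strictly less than a tolerance (default 10 samples = 80 ms at 125 Hz),
otherwise it is discarded from the MAE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from scipy.signal import find_peaks, periodogram

from .wnet import pearson_r


@dataclass
class FeaturePoints:
    """Per-beat systolic peaks and diastolic troughs of an ABP signal."""

    sbp_indices: np.ndarray
    sbp_values: np.ndarray
    dbp_indices: np.ndarray
    dbp_values: np.ndarray

    def __post_init__(self) -> None:
        self.sbp_indices = np.asarray(self.sbp_indices, dtype=np.int64)
        self.dbp_indices = np.asarray(self.dbp_indices, dtype=np.int64)
        self.sbp_values = np.asarray(self.sbp_values, dtype=np.float64)
        self.dbp_values = np.asarray(self.dbp_values, dtype=np.float64)
        for idx in (self.sbp_indices, self.dbp_indices):
            if len(idx) > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError("feature indices must be strictly increasing")

    @property
    def n_sbp(self) -> int:
        return len(self.sbp_indices)

    @property
    def n_dbp(self) -> int:
        return len(self.dbp_indices)


@dataclass
class EvalReport:
    """The five similarity measures for one (reference, reconstructed) pair.

    ``mae_sbp`` / ``mae_dbp`` are ``None`` when no feature pair could be
    matched (reported missing, never as zero).
    """

    rmse: float
    pearson_r: float
    mae_sbp: float | None
    mae_dbp: float | None
    dtw_norm: float
    n_matched_sbp: int
    n_matched_dbp: int
    n_discarded_sbp: int
    n_discarded_dbp: int

    COLUMNS = ("rmse", "mae_sbp", "mae_dbp", "pearson_r", "dtw_norm",
               "n_matched_sbp", "n_matched_dbp", "n_discarded_sbp", "n_discarded_dbp")

    def to_row(self) -> list:
        return [getattr(self, c) for c in self.COLUMNS]


def rmse(ref: Sequence[float], rec: Sequence[float]) -> float:
    """Root mean square error, in the units of the inputs (mmHg for ABP)."""
    ref = np.asarray(ref, dtype=np.float64)
    rec = np.asarray(rec, dtype=np.float64)
    if ref.shape != rec.shape or ref.size == 0:
        raise ValueError("rmse requires equal-length non-empty sequences")
    return float(np.sqrt(np.mean((ref - rec) ** 2)))


def _estimate_hr_hz(abp: np.ndarray, fs: float) -> float:
    """Dominant spectral peak of the mean-removed signal in the 0.5-3 Hz band."""
    f, pxx = periodogram(abp - abp.mean(), fs=fs)
    band = (f >= 0.5) & (f <= 3.0)
    if not np.any(band) or np.all(pxx[band] == 0):
        return 1.0  # fall back to 60 bpm
    return float(f[band][np.argmax(pxx[band])])


def delineate(abp: Sequence[float], fs: float, prominence: float = 10.0) -> FeaturePoints:
    """Extract systolic peaks and diastolic troughs from an ABP signal.

    Systolic peaks are local maxima with at least ``prominence`` mmHg of
    prominence, separated by at least 40% of the estimated beat period
    (heart rate from the dominant 0.5-3 Hz spectral peak).  Diastolic troughs
    are the global minima of the stretches between consecutive systolic peaks
    and of the flanking stretches before the first and after the last peak,
    which enforces the peak/trough alternation.  A signal with no qualifying
    peaks yields empty feature sets, not an error.
    """
    abp = np.asarray(abp, dtype=np.float64)
    if len(abp) < 2 * fs:
        raise ValueError("delineate requires at least ~2 s of signal")
    hr_hz = _estimate_hr_hz(abp, fs)
    min_dist = max(1, int(0.4 * fs / hr_hz))
    peaks, _ = find_peaks(abp, prominence=prominence, distance=min_dist)
    if len(peaks) == 0:
        empty = np.array([], dtype=np.int64)
        return FeaturePoints(empty, np.array([]), empty.copy(), np.array([]))
    troughs = []
    if peaks[0] > 0:
        troughs.append(int(np.argmin(abp[:peaks[0]])))
    for i in range(len(peaks) - 1):
        lo, hi = peaks[i], peaks[i + 1]
        troughs.append(lo + int(np.argmin(abp[lo:hi])))
    if peaks[-1] + 1 < len(abp):
        troughs.append(peaks[-1] + 1 + int(np.argmin(abp[peaks[-1] + 1:])))
    troughs = np.asarray(troughs, dtype=np.int64)
    return FeaturePoints(
        sbp_indices=peaks, sbp_values=abp[peaks],
        dbp_indices=troughs, dbp_values=abp[troughs],
    )


def _match_kind(ref_idx: np.ndarray, ref_val: np.ndarray,
                rec_idx: np.ndarray, rec_val: np.ndarray,
                tol_samples: int) -> tuple[list[tuple[float, float]], int]:
    """Greedy nearest-first matching in reference order; each reconstructed
    feature is used at most once; distance must be strictly < tol_samples."""
    pairs: list[tuple[float, float]] = []
    used = np.zeros(len(rec_idx), dtype=bool)
    discarded = 0
    for i in range(len(ref_idx)):
        free = np.nonzero(~used)[0]
        if len(free) == 0:
            discarded += 1
            continue
        d = np.abs(rec_idx[free] - ref_idx[i])
        j = free[int(np.argmin(d))]
        if abs(int(rec_idx[j]) - int(ref_idx[i])) < tol_samples:
            pairs.append((float(ref_val[i]), float(rec_val[j])))
            used[j] = True
        else:
            discarded += 1
    return pairs, discarded


def match_features(
    ref_pts: FeaturePoints, rec_pts: FeaturePoints, tol_samples: int = 10
) -> dict[str, tuple[list[tuple[float, float]], int]]:
    """Correspondence matching of systolic and diastolic feature points.

    Returns, per feature kind (``"sbp"``, ``"dbp"``), the matched
    (reference value, reconstructed value) pairs and the count of reference
    features discarded for lack of a counterpart within ``tol_samples``.
    """
    if tol_samples < 0:
        raise ValueError("tol_samples must be non-negative")
    return {
        "sbp": _match_kind(ref_pts.sbp_indices, ref_pts.sbp_values,
                           rec_pts.sbp_indices, rec_pts.sbp_values, tol_samples),
        "dbp": _match_kind(ref_pts.dbp_indices, ref_pts.dbp_values,
                           rec_pts.dbp_indices, rec_pts.dbp_values, tol_samples),
    }


def feature_recall(true_indices, true_values, found_indices, found_values,
                   tol_samples: int = 2) -> float:
    """Fraction of true feature points recovered by a delineation.

    A true point counts as recovered when a found point lies within
    ``tol_samples`` of its index and carries exactly its value (appropriate
    for noise-free signals where extrema are sharp).
    """
    true_indices = np.asarray(true_indices)
    found_indices = np.asarray(found_indices)
    found_values = np.asarray(found_values)
    if len(true_indices) == 0:
        return 1.0
    hit = 0
    for idx, val in zip(true_indices, np.asarray(true_values)):
        d = np.abs(found_indices - idx)
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] <= tol_samples and found_values[j] == val:
            hit += 1
    return hit / len(true_indices)


def mae_features(matched_pairs: Sequence[tuple[float, float]]) -> float:
    """Mean absolute difference over matched feature pairs (mmHg)."""
    if len(matched_pairs) == 0:
        raise ValueError("mae undefined with zero matched pairs")
    arr = np.asarray(matched_pairs, dtype=np.float64)
    return float(np.mean(np.abs(arr[:, 0] - arr[:, 1])))


@njit(cache=False)
def _dtw_core(x: np.ndarray, y: np.ndarray) -> float:  # pragma: no cover - numba
    n, m = len(x), len(y)
    prev = np.empty(m + 1)
    curr = np.empty(m + 1)
    prev[:] = np.inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        curr[0] = np.inf
        xi = x[i - 1]
        for j in range(1, m + 1):
            c = abs(xi - y[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = c + best
        prev, curr = curr, prev
    return prev[m]


def dtw_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Dynamic-time-warping distance with local cost |x_i - y_j|.

    Classic symmetric step pattern — predecessors (i-1,j), (i,j-1),
    (i-1,j-1) — no warping window, each visited cell's cost counted once;
    the minimal cumulative cost of a monotone path from (1,1) to (N,M).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("dtw_distance requires non-empty sequences")
    return float(_dtw_core(x, y))


def normalized_dtw(ref: Sequence[float], rec: Sequence[float]) -> float:
    """DTW distance divided by the summed lengths of the two signals (2N)."""
    ref = np.asarray(ref, dtype=np.float64)
    rec = np.asarray(rec, dtype=np.float64)
    if ref.size == 0 or rec.size == 0:
        raise ValueError("normalized_dtw requires non-empty sequences")
    if ref.size != rec.size:
        raise ValueError("reference and reconstruction must cover the same range")
    return dtw_distance(ref, rec) / (2.0 * ref.size)


def evaluate(
    ref_abp: Sequence[float],
    rec_abp: Sequence[float],
    fs: float = 125.0,
    tol_samples: int = 10,
    prominence: float = 10.0,
) -> EvalReport:
    """Assemble the five-measure report for one reference/reconstruction pair."""
    ref_abp = np.asarray(ref_abp, dtype=np.float64)
    rec_abp = np.asarray(rec_abp, dtype=np.float64)
    if ref_abp.shape != rec_abp.shape:
        raise ValueError("reference and reconstruction must have equal length")
    ref_pts = delineate(ref_abp, fs, prominence=prominence)
    rec_pts = delineate(rec_abp, fs, prominence=prominence)
    matches = match_features(ref_pts, rec_pts, tol_samples)
    sbp_pairs, sbp_disc = matches["sbp"]
    dbp_pairs, dbp_disc = matches["dbp"]
    return EvalReport(
        rmse=rmse(ref_abp, rec_abp),
        pearson_r=pearson_r(ref_abp, rec_abp),
        mae_sbp=mae_features(sbp_pairs) if sbp_pairs else None,
        mae_dbp=mae_features(dbp_pairs) if dbp_pairs else None,
        dtw_norm=normalized_dtw(ref_abp, rec_abp),
        n_matched_sbp=len(sbp_pairs),
        n_matched_dbp=len(dbp_pairs),
        n_discarded_sbp=sbp_disc,
        n_discarded_dbp=dbp_disc,
    )
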