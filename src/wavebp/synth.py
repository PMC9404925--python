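"""Synthetic paired PPG/ABP records with per-beat ground truth.

Each beat is a sum of three Gaussian lobes in beat phase — systolic wave,
dicrotic shoulder and reflection wave — which reproduces the canonical
arterial-pulse morphology (systolic upstroke, dicrotic notch, diastolic
reflection).  The ABP channel is the beat train scaled per beat to
[DBP, SBP] in mmHg; the PPG channel is the same beat train with its own
lobe weights, delayed by a fixed number of samples (pulse transit to the
periphery), plus a linear baseline drift and additive white noise.
Beat-to-beat heart-rate jitter and optional shortened (ectopic) beats are
supported.  Ground truth marks the true systolic/diastolic extrema of the
noise-free ABP, which makes the delineator and the end-to-end pipeline
verifiable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import SignalRecord

#: (amplitude, phase center, phase width) per lobe: systolic, dicrotic, reflection
DEFAULT_ABP_LOBES = ((1.0, 0.30, 0.09), (0.35, 0.55, 0.06), (0.40, 0.72, 0.10))
#: the PPG shares the beat's lobe timing but mixes the lobes with its own
#: weights, so the configured sample delay is the only PPG-vs-ABP lag
DEFAULT_PPG_LOBES = ((1.0, 0.30, 0.10), (0.30, 0.55, 0.07), (0.45, 0.72, 0.11))


class TemplateConfigError(ValueError):
    """Raised when lobe parameters cannot produce a valid pulse morphology."""


@dataclass
class SynthConfig:
    """Parameters of one synthetic subject.

    Defaults are a normotensive adult: 120/80 mmHg, 75 bpm with mild
    beat-to-beat jitter, a 20-sample (160 ms at 125 Hz) PPG lag, a slow
    linear PPG baseline drift and a small amount of white noise.
    """

    fs: float = 125.0
    duration_s: float = 480.0
    hr_mean: float = 75.0
    hr_sd: float = 3.0
    sbp: float = 120.0
    dbp: float = 80.0
    wave_params: Sequence[tuple[float, float, float]] = DEFAULT_ABP_LOBES
    ppg_wave_params: Sequence[tuple[float, float, float]] = DEFAULT_PPG_LOBES
    ppg_delay_samples: int = 20
    ppg_drift_slope: float = 1e-5
    noise_sd: float = 0.02
    arrhythmia_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dbp < self.sbp <= 200):
            raise ValueError(f"require 0 < dbp < sbp <= 200, got dbp={self.dbp} sbp={self.sbp}")
        if self.hr_mean <= 0:
            raise ValueError("hr_mean must be positive")
        if self.hr_sd < 0:
            raise ValueError("hr_sd must be non-negative")
        if not (0.0 <= self.arrhythmia_prob <= 1.0):
            raise ValueError("arrhythmia_prob must lie in [0, 1]")
        if self.ppg_delay_samples < 0:
            raise ValueError("ppg_delay_samples must be >= 0")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")


@dataclass
class GroundTruth:
    """True per-beat feature points of the noise-free ABP."""

    beat_onsets: np.ndarray
    sbp_indices: np.ndarray
    sbp_values: np.ndarray
    dbp_indices: np.ndarray
    dbp_values: np.ndarray
    delay_samples: int

    @property
    def n_beats(self) -> int:
        return len(self.beat_onsets)


def _lobe_sum(wave_params, phase: np.ndarray) -> np.ndarray:
    out = np.zeros_like(phase)
    for amp, center, width in wave_params:
        out += amp * np.exp(-((phase - center) ** 2) / (2.0 * width**2))
    return out


def generate_beat_template(
    wave_params: Sequence[tuple[float, float, float]],
    n_points: int,
    notch_depth: float = 0.99,
) -> np.ndarray:
    """One normalized pulse period sampled at ``n_points``.

    The template is min-max normalized to [0, 1] and phase-aligned so the
    beat starts at its diastolic minimum (sample 0).  The global maximum must
    fall inside the systolic lobe and a dicrotic notch — an interior local
    minimum whose flanking maxima both exceed it by more than the
    ``notch_depth`` ratio — must exist between the systolic and reflection
    lobes, otherwise a :class:`TemplateConfigError` is raised.
    """
    if n_points < 8:
        raise ValueError("n_points must be at least 8")
    params = list(wave_params)
    if len(params) != 3:
        raise TemplateConfigError("exactly three lobes (systolic, dicrotic, reflection) required")
    if any(p[0] <= 0 for p in params):
        raise TemplateConfigError("all lobe amplitudes must be positive")
    sys_c, dic_c, ref_c = (p[1] for p in params)
    if not (sys_c < dic_c and sys_c < ref_c):
        raise TemplateConfigError("systolic lobe center must precede dicrotic and reflection lobes")

    phase = np.arange(n_points) / n_points
    raw = _lobe_sum(params, phase)

    # global max must be carried by the systolic lobe (nearest lobe center)
    peak_phase = phase[int(np.argmax(raw))]
    centers = np.array([sys_c, dic_c, ref_c])
    if int(np.argmin(np.abs(centers - peak_phase))) != 0:
        raise TemplateConfigError("systolic lobe does not carry the global maximum")

    # start the beat at its diastolic minimum
    raw = np.roll(raw, -int(np.argmin(raw)))
    tpl = (raw - raw.min()) / (raw.max() - raw.min())

    # require a dicrotic notch: an interior local min after the systolic peak
    # flanked by maxima that both exceed it by the strictness ratio
    peak = int(np.argmax(tpl))
    interior = tpl[1:-1]
    is_min = (interior < tpl[:-2]) & (interior <= tpl[2:])
    notch_found = False
    for i in np.nonzero(is_min)[0] + 1:
        if i <= peak:
            continue
        left_max = tpl[peak:i].max()
        right_max = tpl[i:].max()
        if tpl[i] < notch_depth * min(left_max, right_max):
            notch_found = True
            break
    if not notch_found:
        raise TemplateConfigError(
            "no dicrotic notch: no interior local minimum below "
            f"{notch_depth} of its neighboring maxima"
        )
    return tpl


def _beat_periods(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-beat period lengths in samples until the record duration is covered."""
    n_total = int(round(config.fs * config.duration_s))
    periods: list[int] = []
    covered = 0
    while covered < n_total:
        hr = config.hr_mean
        if config.hr_sd > 0:
            hr = float(np.clip(rng.normal(config.hr_mean, config.hr_sd),
                               config.hr_mean - 3 * config.hr_sd,
                               config.hr_mean + 3 * config.hr_sd))
        period = 60.0 * config.fs / hr
        if config.arrhythmia_prob > 0 and rng.random() < config.arrhythmia_prob:
            period *= 0.6  # ectopic: shortened beat
        n = max(8, int(round(period)))
        periods.append(n)
        covered += n
    if len(periods) == 1 and covered < 8:
        raise ValueError("duration too short for a single beat")
    return np.array(periods, dtype=np.int64)


def generate_record(config: SynthConfig) -> tuple[SignalRecord, GroundTruth]:
    """Generate one synthetic subject: paired PPG/ABP plus ground truth.

    The same seed yields bit-identical output.  With ``noise_sd = 0`` the
    ABP extrema per beat equal ``config.sbp`` / ``config.dbp`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    n_total = int(round(config.fs * config.duration_s))
    if n_total < 8:
        raise ValueError("duration too short for a single beat")
    periods = _beat_periods(config, rng)

    abp = np.empty(sum(periods))
    ppg = np.empty(sum(periods))
    onsets = np.empty(len(periods), dtype=np.int64)
    sbp_idx = np.empty(len(periods), dtype=np.int64)
    pos = 0
    for b, n in enumerate(periods):
        tpl_abp = generate_beat_template(config.wave_params, n)
        tpl_ppg = generate_beat_template(config.ppg_wave_params, n)
        abp[pos:pos + n] = config.dbp + (config.sbp - config.dbp) * tpl_abp
        ppg[pos:pos + n] = tpl_ppg
        onsets[b] = pos
        sbp_idx[b] = pos + int(np.argmax(tpl_abp))
        pos += n

    abp = abp[:n_total]
    ppg = ppg[:n_total]
    # last beat may be truncated; keep only beats whose systolic peak survived
    keep = sbp_idx < n_total
    onsets, sbp_idx = onsets[keep], sbp_idx[keep]

    gt = GroundTruth(
        beat_onsets=onsets,
        sbp_indices=sbp_idx,
        sbp_values=abp[sbp_idx].copy(),
        dbp_indices=onsets.copy(),  # beats are phase-aligned to start at the minimum
        dbp_values=abp[onsets].copy(),
        delay_samples=config.ppg_delay_samples,
    )

    d = config.ppg_delay_samples
    if d > 0:
        ppg = np.concatenate([np.full(d, ppg[0]), ppg])[:n_total]
    ppg = ppg + config.ppg_drift_slope * np.arange(n_total)
    if config.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, config.noise_sd, n_total)
        abp = abp + rng.normal(0.0, config.noise_sd, n_total)

    rec = SignalRecord(record_id=f"synth-{config.seed}", fs=config.fs, ppg=ppg, abp=abp)
    return rec, gt


def generate_dataset(configs: Sequence[SynthConfig]) -> list[tuple[SignalRecord, GroundTruth]]:
    """Element-wise :func:`generate_record`; errors name the offending config index."""
    out = []
    for i, cfg in enumerate(configs):
        try:
            out.append(generate_record(cfg))
        except Exception as exc:
            raise type(exc)(f"config {i}: {exc}") from exc
    return out


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Sidecar file: one row ``beat_index,sbp_index,sbp_value,dbp_index,dbp_value`` per beat."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# beat_index,sbp_index,sbp_value,dbp_index,dbp_value\n")
        for b in range(gt.n_beats):
            fh.write(
                f"{b},{gt.sbp_indices[b]},{float(gt.sbp_values[b])!r},"
                f"{gt.dbp_indices[b]},{float(gt.dbp_values[b])!r}\n"
            )
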