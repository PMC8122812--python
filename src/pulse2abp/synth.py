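"""Synthetic paired PPG/ABP waveform generation.

Produces morphologically realistic pulse pairs with known ground truth
(SBP, DBP, phase lag, beat times, noise level) so that every downstream
stage — filtering, alignment, quality control, model training and
BHS/AAMI evaluation — can be exercised without access to an ICU waveform
database.

Each beat is the sum of two Gaussian lobes: a systolic lobe centred at
30% of the pulse period and a dicrotic (reflection) lobe at 65% of the
period.  This reproduces the four canonical pulse landmarks (foot,
systolic peak, dicrotic notch, diastolic peak) with two shape
parameters.  The PPG channel's morphology is deterministically coupled
to the blood-pressure targets — the systolic lobe narrows as SBP rises
(a stiffer vessel transmits a faster pulse) and the dicrotic lobe grows
with DBP (stronger reflection under higher diastolic tone) — so that a
learnable PPG→ABP map exists even after per-signal amplitude
normalization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SAMPLING_RATE_HZ = 125.0

CORRUPTION_MODES = ("none", "flatline", "dropout_burst", "saturation")

#: fraction of the pulse period at which each lobe is centred
_SYS_CENTER_FRAC = 0.30
_DIC_CENTER_FRAC = 0.65
_DIC_WIDTH_FRAC = 0.12


class SynthConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters for one generated segment.

    Amplitude-type noise parameters are relative to each channel's pulse
    amplitude: the ABP channel receives Gaussian noise with standard
    deviation ``noise_sd * (sbp_mmHg - dbp_mmHg)`` mmHg, the PPG channel
    (unit pulse amplitude, arbitrary units) receives ``noise_sd``.
    """

    sampling_rate_hz: float = SAMPLING_RATE_HZ
    segment_len: int = 1024
    heart_rate_bpm: float = 75.0
    hr_jitter: float = 0.02
    sbp_mmHg: float = 120.0
    dbp_mmHg: float = 80.0
    dicrotic_rel_amp: float = 0.25
    lag_samples: int = 0
    noise_sd: float = 0.0
    baseline_wander_amp: float = 0.0
    corruption: str = "none"
    seed: int = 0

    @property
    def pulse_period_samples(self) -> float:
        return 60.0 / self.heart_rate_bpm * self.sampling_rate_hz

    def validate(self) -> None:
        if self.sampling_rate_hz != SAMPLING_RATE_HZ:
            raise SynthConfigError(
                f"sampling_rate_hz must be {SAMPLING_RATE_HZ:g}, got "
                f"{self.sampling_rate_hz:g}"
            )
        if self.dbp_mmHg >= self.sbp_mmHg:
            raise SynthConfigError(
                f"dbp_mmHg ({self.dbp_mmHg:g}) must be < sbp_mmHg "
                f"({self.sbp_mmHg:g})"
            )
        if self.noise_sd < 0:
            raise SynthConfigError(f"noise_sd must be >= 0, got {self.noise_sd:g}")
        if self.baseline_wander_amp < 0:
            raise SynthConfigError("baseline_wander_amp must be >= 0")
        if not 0 <= self.dicrotic_rel_amp < 1:
            raise SynthConfigError(
                f"dicrotic_rel_amp must be in [0, 1), got {self.dicrotic_rel_amp:g}"
            )
        period = self.pulse_period_samples
        if not 0 <= self.lag_samples < period:
            raise SynthConfigError(
                f"lag_samples ({self.lag_samples}) must be >= 0 and shorter than "
                f"one pulse period ({period:.1f} samples)"
            )
        if self.segment_len < 2 * period:
            raise SynthConfigError(
                f"segment_len ({self.segment_len}) must cover at least two pulse "
                f"periods ({2 * period:.1f} samples)"
            )
        if self.corruption not in CORRUPTION_MODES:
            raise SynthConfigError(
                f"corruption must be one of {CORRUPTION_MODES}, got "
                f"{self.corruption!r}"
            )
        if not 0 <= self.hr_jitter < 0.2:
            raise SynthConfigError("hr_jitter must be in [0, 0.2)")


@dataclass
class PairedSegment:
    """One fixed-length PPG/ABP pair with provenance metadata."""

    ppg: np.ndarray
    abp: np.ndarray
    sampling_rate_hz: float
    subject_id: str = "s0000"
    segment_id: str = "s0000_seg0000"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=np.float64)
        self.abp = np.asarray(self.abp, dtype=np.float64)
        if self.ppg.shape != self.abp.shape or self.ppg.ndim != 1:
            raise ValueError(
                f"ppg and abp must be equal-length 1-D series, got shapes "
                f"{self.ppg.shape} and {self.abp.shape}"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")

    def __len__(self) -> int:
        return self.ppg.size


def _ppg_sys_width_frac(sbp: float) -> float:
    # narrower systolic lobe at higher systolic pressure
    return float(np.clip(0.13 - 0.07 * (sbp - 80.0) / 100.0, 0.05, 0.15))


def _ppg_dic_amp(dbp: float) -> float:
    # larger reflection lobe at higher diastolic pressure
    return float(np.clip(0.15 + 0.55 * (dbp - 60.0) / 70.0, 0.05, 0.85))


def _beat_onsets(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Beat onset times (in samples) covering the segment with margin."""
    period = config.pulse_period_samples
    n_beats = int(np.ceil(config.segment_len / period)) + 4
    periods = period * (1.0 + config.hr_jitter * rng.standard_normal(n_beats))
    onsets = np.concatenate([[-2.0 * period], -2.0 * period + np.cumsum(periods)])
    return onsets


def _pulse_train(
    n: int,
    onsets: np.ndarray,
    sys_width_frac: float,
    dic_amp: float,
    period: float,
) -> np.ndarray:
    """Sum of per-beat systolic + dicrotic Gaussian lobes on an n-sample grid."""
    t = np.arange(n, dtype=np.float64)
    out = np.zeros(n)
    sig_s = sys_width_frac * period
    sig_d = _DIC_WIDTH_FRAC * period
    for onset in onsets:
        c_s = onset + _SYS_CENTER_FRAC * period
        c_d = onset + _DIC_CENTER_FRAC * period
        lo = max(0, int(onset - period))
        hi = min(n, int(onset + 2 * period))
        if hi <= lo:
            continue
        w = t[lo:hi]
        out[lo:hi] += np.exp(-0.5 * ((w - c_s) / sig_s) ** 2)
        out[lo:hi] += dic_amp * np.exp(-0.5 * ((w - c_d) / sig_d) ** 2)
    return out


def _systolic_peak_indices(
    onsets: np.ndarray, period: float, n: int, lag: int
) -> np.ndarray:
    """Ground-truth systolic peak sample indices after the lag shift."""
    centers = np.round(onsets + _SYS_CENTER_FRAC * period).astype(int)
    centers = centers[(centers >= 0) & (centers < n)]
    return np.sort((centers + lag) % n)


def _apply_corruption(
    ppg: np.ndarray, abp: np.ndarray, mode: str, rng: np.random.Generator
) -> None:
    n = ppg.size
    if mode == "flatline":
        ppg[:] = ppg[0]
    elif mode == "dropout_burst":
        burst = int(0.45 * n)
        start = int(rng.integers(0, n - burst))
        ppg[start : start + burst] = 0.0
    elif mode == "saturation":
        # pressure transducer railed high for a stretch of the segment
        burst = int(0.20 * n)
        start = int(rng.integers(0, n - burst))
        abp[start : start + burst] = 195.0


def generate_segment(config: SynthConfig) -> PairedSegment:
    """Generate one paired PPG/ABP segment from ``config``.

    Deterministic for a fixed seed.  With ``noise_sd == 0`` and
    ``corruption == "none"`` the ABP extrema equal the configured
    SBP/DBP exactly (affine rescaling after waveform synthesis); the PPG
    channel is circularly shifted by ``lag_samples`` so the PPG lags the
    ABP, as in simultaneously recorded monitor channels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.segment_len
    period = config.pulse_period_samples
    onsets = _beat_onsets(config, rng)
    t = np.arange(n) / config.sampling_rate_hz

    # both channels share the SBP-dependent systolic width (the pressure
    # pulse narrows with vessel stiffness just as its optical echo does);
    # the ABP dicrotic amplitude is the configured one while the PPG's
    # tracks DBP
    abp_shape = _pulse_train(
        n, onsets, _ppg_sys_width_frac(config.sbp_mmHg), config.dicrotic_rel_amp,
        period,
    )
    ppg_shape = _pulse_train(
        n,
        onsets,
        _ppg_sys_width_frac(config.sbp_mmHg),
        _ppg_dic_amp(config.dbp_mmHg),
        period,
    )

    if config.baseline_wander_amp > 0:
        f_w = rng.uniform(0.1, 0.45)  # Hz, below the 0.5 Hz filter edge
        phase_a, phase_p = rng.uniform(0, 2 * np.pi, size=2)
        abp_shape = abp_shape + config.baseline_wander_amp * np.sin(
            2 * np.pi * f_w * t + phase_a
        )
        ppg_shape = ppg_shape + config.baseline_wander_amp * np.sin(
            2 * np.pi * f_w * t + phase_p
        )

    # affine rescale so min -> DBP and max -> SBP exactly
    lo, hi = abp_shape.min(), abp_shape.max()
    abp = config.dbp_mmHg + (abp_shape - lo) * (
        (config.sbp_mmHg - config.dbp_mmHg) / (hi - lo)
    )

    ppg = ppg_shape - ppg_shape.mean()  # arbitrary units centred near 0
    ppg = np.roll(ppg, config.lag_samples)

    if config.noise_sd > 0:
        pulse_pressure = config.sbp_mmHg - config.dbp_mmHg
        abp = abp + rng.normal(0.0, config.noise_sd * pulse_pressure, n)
        ppg = ppg + rng.normal(0.0, config.noise_sd, n)

    if config.corruption != "none":
        _apply_corruption(ppg, abp, config.corruption, rng)

    peaks = _systolic_peak_indices(onsets, period, n, config.lag_samples)
    meta = {
        "config": config,
        "sbp_mmHg": config.sbp_mmHg,
        "dbp_mmHg": config.dbp_mmHg,
        "lag_samples": config.lag_samples,
        "corruption": config.corruption,
        "systolic_peaks": peaks,
    }
    return PairedSegment(
        ppg=ppg,
        abp=abp,
        sampling_rate_hz=config.sampling_rate_hz,
        meta=meta,
    )


# Per-subject draw ranges for dataset generation.  Chosen to stay inside
# the 80–180 / 60–130 mmHg retention bounds with margin so that clean
# segments always survive quality control.
DEFAULT_SBP_RANGE = (95.0, 172.0)
DEFAULT_DBP_RANGE = (63.0, 105.0)
DEFAULT_HR_RANGE = (65.0, 85.0)
DEFAULT_LAG_RANGE = (0, 55)
MIN_PULSE_PRESSURE = 25.0


def generate_dataset(
    config: SynthConfig,
    n_subjects: int,
    segments_per_subject: int,
    corrupt_frac: float = 0.0,
    corruption: str = "mix",
    sbp_range: tuple[float, float] = DEFAULT_SBP_RANGE,
    dbp_range: tuple[float, float] = DEFAULT_DBP_RANGE,
    hr_range: tuple[float, float] = DEFAULT_HR_RANGE,
    lag_range: tuple[int, int] = DEFAULT_LAG_RANGE,
) -> list[PairedSegment]:
    """Generate a reproducible multi-subject dataset.

    Per-subject heart rate, SBP/DBP and phase lag are drawn from the
    given ranges with a per-subject sub-seed derived from
    ``config.seed``; per-segment SBP/DBP wobble ±2 mmHg around the
    subject mean.  A seeded ``corrupt_frac`` fraction of segments is
    corrupted (mode cycling through flatline/dropout_burst/saturation
    when ``corruption == "mix"``); corrupted segments are labelled in
    ``meta["corruption"]``.
    """
    if n_subjects < 1 or segments_per_subject < 1:
        raise SynthConfigError("n_subjects and segments_per_subject must be >= 1")
    if not 0 <= corrupt_frac <= 1:
        raise SynthConfigError("corrupt_frac must be in [0, 1]")
    if corruption != "mix" and corruption not in CORRUPTION_MODES[1:]:
        raise SynthConfigError(f"unknown corruption mode {corruption!r}")

    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(n_subjects + 1)
    pick_rng = np.random.default_rng(subject_seeds[-1])

    n_total = n_subjects * segments_per_subject
    n_corrupt = int(round(corrupt_frac * n_total))
    corrupt_ids = set(
        pick_rng.choice(n_total, size=n_corrupt, replace=False).tolist()
    )
    modes = CORRUPTION_MODES[1:]

    segments: list[PairedSegment] = []
    flat_index = 0
    for si in range(n_subjects):
        s_rng = np.random.default_rng(subject_seeds[si])
        hr = s_rng.uniform(*hr_range)
        dbp = s_rng.uniform(*dbp_range)
        sbp_lo = max(sbp_range[0], dbp + MIN_PULSE_PRESSURE)
        sbp = s_rng.uniform(sbp_lo, sbp_range[1])
        max_lag_subject = min(
            lag_range[1], int(60.0 / hr * config.sampling_rate_hz) - 1
        )
        lag = int(s_rng.integers(lag_range[0], max_lag_subject + 1))
        subject_id = f"s{si:04d}"
        for gi in range(segments_per_subject):
            seg_sbp = float(np.clip(sbp + s_rng.normal(0, 2.0), 82.0, 178.0))
            seg_dbp = float(
                np.clip(dbp + s_rng.normal(0, 2.0), 61.0, seg_sbp - 15.0)
            )
            if flat_index in corrupt_ids:
                mode = (
                    modes[flat_index % len(modes)] if corruption == "mix" else corruption
                )
            else:
                mode = "none"
            seg_cfg = replace(
                config,
                heart_rate_bpm=hr,
                sbp_mmHg=seg_sbp,
                dbp_mmHg=seg_dbp,
                lag_samples=lag,
                corruption=mode,
                seed=int(s_rng.integers(0, 2**31 - 1)),
            )
            seg = generate_segment(seg_cfg)
            seg.subject_id = subject_id
            seg.segment_id = f"{subject_id}_seg{gi:04d}"
            segments.append(seg)
            flat_index += 1
    return segments


def dataset_digest(segments: Sequence[PairedSegment]) -> str:
    """SHA-256 digest over all waveform samples, for reproducibility checks."""
    h = hashlib.sha256()
    for seg in segments:
        h.update(seg.segment_id.encode())
        h.update(np.ascontiguousarray(seg.ppg).tobytes())
        h.update(np.ascontiguousarray(seg.abp).tobytes())
    return h.hexdigest()
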