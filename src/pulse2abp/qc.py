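"""Quality control: SBP/DBP bounds, morphology correlation, peak detectability.

Four retention rules are applied to every aligned segment; a segment is
kept only if all four hold:

1. systolic pressure (segment maximum of the ABP) not above 180 mmHg and
   not below 80 mmHg — strict "more than"/"less than", so 180 and 80 pass;
2. diastolic pressure (segment minimum) not above 130 mmHg and not below
   60 mmHg;
3. Pearson correlation between the aligned PPG and ABP at least 0.8;
4. at least one usable PPG systolic peak.

Every rule is always evaluated and reported, so the elimination funnel
can be audited per reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats

SBP_MAX = 180.0
SBP_MIN = 80.0
DBP_MAX = 130.0
DBP_MIN = 60.0
MIN_CORRELATION = 0.8
BPM_RANGE = (40.0, 180.0)
ROLLING_MEAN_S = 0.75


@dataclass(frozen=True)
class QCThresholds:
    sbp_max: float = SBP_MAX
    sbp_min: float = SBP_MIN
    dbp_max: float = DBP_MAX
    dbp_min: float = DBP_MIN
    min_r: float = MIN_CORRELATION


@dataclass
class QCReport:
    segment_id: str
    sbp_mmHg: float
    dbp_mmHg: float
    pearson_r: float
    peaks_found: int
    passed: bool
    failure_reasons: list[str] = field(default_factory=list)


def extract_sbp(abp: np.ndarray) -> float:
    """Systolic pressure: the maximum of the ABP segment, in mmHg."""
    abp = np.asarray(abp, dtype=np.float64)
    if abp.size == 0:
        raise ValueError("cannot extract SBP from an empty segment")
    return float(abp.max())


def extract_dbp(abp: np.ndarray) -> float:
    """Diastolic pressure: the minimum of the ABP segment, in mmHg."""
    abp = np.asarray(abp, dtype=np.float64)
    if abp.size == 0:
        raise ValueError("cannot extract DBP from an empty segment")
    return float(abp.min())


def pearson_r(a: np.ndarray, p: np.ndarray) -> float:
    """Product-moment correlation between two equal-length series."""
    a = np.asarray(a, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if a.shape != p.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("inputs must be equal-length 1-D series of length >= 3")
    if a.std() < 1e-12 or p.std() < 1e-12:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(a, p).statistic)


#: threshold elevations swept by the adaptive detector, as a percentage
#: of the signal's mean-to-maximum span above the rolling mean
THRESHOLD_SWEEP_PCT = (0, 5, 10, 15, 20, 25, 30, 40, 50)


def _peaks_above(ppg: np.ndarray, threshold: np.ndarray, fs: float) -> np.ndarray:
    above = ppg > threshold
    if not above.any():
        return np.array([], dtype=int)
    labels, n_regions = ndimage.label(above)
    candidates = np.array(
        ndimage.maximum_position(ppg, labels, index=range(1, n_regions + 1))
    ).ravel()
    candidates = np.sort(candidates.astype(int))
    # a maximum on the array boundary is a truncated partial beat
    candidates = candidates[(candidates > 0) & (candidates < ppg.size - 1)]
    # merge peaks closer than the 180 bpm refractory interval
    min_gap = fs * 60.0 / BPM_RANGE[1]
    kept: list[int] = []
    for idx in candidates:
        if kept and idx - kept[-1] < min_gap:
            if ppg[idx] > ppg[kept[-1]]:
                kept[-1] = idx
        else:
            kept.append(idx)
    return np.array(kept, dtype=int)


def detect_systolic_peaks(ppg: np.ndarray, fs: float = 125.0) -> np.ndarray:
    """Systolic peak indices via a moving-average adaptive threshold.

    The signal is compared against its 0.75 s rolling mean raised by a
    swept percentage of the mean-to-maximum span; region maxima above
    the threshold are candidate peaks, and candidates implying an
    instantaneous rate above 180 bpm are merged (the higher peak wins).
    Among sweep settings whose implied rate lies in 40–180 bpm the one
    with the most regular inter-peak intervals is kept — secondary
    (dicrotic) waves crossing a low threshold produce irregular interval
    patterns and are rejected this way.  Callers should treat fewer than
    two survivors, or a failed periodicity check, as "no usable peak".
    """
    ppg = np.asarray(ppg, dtype=np.float64)
    if ppg.size == 0:
        return np.array([], dtype=int)
    win = max(3, int(round(ROLLING_MEAN_S * fs)))
    rolling = ndimage.uniform_filter1d(ppg, size=win, mode="nearest")
    span = float(ppg.max() - ppg.mean())
    best: np.ndarray | None = None
    best_cv = np.inf
    fallback: np.ndarray = np.array([], dtype=int)
    for pct in THRESHOLD_SWEEP_PCT:
        peaks = _peaks_above(ppg, rolling + 0.01 * pct * span, fs)
        if peaks.size > fallback.size:
            fallback = peaks
        if peaks.size < 2:
            continue
        intervals = np.diff(peaks)
        med = float(np.median(intervals))
        bpm = fs * 60.0 / med
        if not BPM_RANGE[0] <= bpm <= BPM_RANGE[1]:
            continue
        cv = float(np.std(intervals) / med)
        if cv < best_cv:
            best, best_cv = peaks, cv
    return best if best is not None else fallback


MIN_PERIODICITY = 0.3


def _autocorr_at(x: np.ndarray, lag: int) -> float:
    """Normalized autocorrelation of a mean-removed series at one lag."""
    x = x - x.mean()
    n = x.size
    denom = float(np.dot(x, x)) * (n - lag) / n
    if denom <= 0 or lag >= n:
        return 0.0
    return float(np.dot(x[: n - lag], x[lag:]) / denom)


def peaks_usable(
    peaks: np.ndarray, fs: float = 125.0, signal: np.ndarray | None = None
) -> bool:
    """Periodicity check: enough peaks, at a plausible and regular rate.

    When the signal is supplied, additionally require that its
    autocorrelation at the median inter-peak interval exceeds 0.3 —
    band-limited noise produces regularly spaced spurious maxima but no
    true periodicity at the detected interval.
    """
    if peaks.size < 2:
        return False
    intervals = np.diff(peaks)
    med = float(np.median(intervals))
    bpm = fs * 60.0 / med
    if not BPM_RANGE[0] <= bpm <= BPM_RANGE[1]:
        return False
    # irregularity beyond severe sinus arrhythmia → not a pulse train
    if float(np.std(intervals) / med) > 0.5:
        return False
    if signal is not None:
        return _autocorr_at(np.asarray(signal, dtype=np.float64), int(round(med))) >= MIN_PERIODICITY
    return True


def qc_filter(
    segment_id: str,
    ppg_aligned: np.ndarray,
    abp_aligned: np.ndarray,
    fs: float = 125.0,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Evaluate all four retention rules on an aligned PPG/ABP pair.

    ``abp_aligned`` must be the raw (unnormalized) pressure in mmHg;
    ``ppg_aligned`` should be the filtered PPG, aligned to the ABP.
    Degenerate signals produce failure reasons, never exceptions.
    """
    th = thresholds or QCThresholds()
    abp_aligned = np.asarray(abp_aligned, dtype=np.float64)
    ppg_aligned = np.asarray(ppg_aligned, dtype=np.float64)
    reasons: list[str] = []

    sbp = extract_sbp(abp_aligned)
    dbp = extract_dbp(abp_aligned)
    if sbp > th.sbp_max or sbp < th.sbp_min:
        reasons.append("sbp_range")
    if dbp > th.dbp_max or dbp < th.dbp_min:
        reasons.append("dbp_range")

    try:
        r = pearson_r(abp_aligned, ppg_aligned)
    except ValueError:
        r = float("nan")
    if not r >= th.min_r:  # NaN fails too
        reasons.append("low_correlation")

    peaks = detect_systolic_peaks(ppg_aligned, fs)
    if not peaks_usable(peaks, fs, signal=ppg_aligned):
        reasons.append("no_peak")

    return QCReport(
        segment_id=segment_id,
        sbp_mmHg=sbp,
        dbp_mmHg=dbp,
        pearson_r=r,
        peaks_found=int(peaks.size),
        passed=not reasons,
        failure_reasons=reasons,
    )
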