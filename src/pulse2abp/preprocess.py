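"""Waveform preprocessing: denoising, normalization, alignment, derivatives.

The chain applied before training is: third-order Butterworth bandpass
(0.5–8 Hz, zero-phase) on the PPG, per-signal z-score normalization,
cross-correlation alignment of the PPG against the reference ABP, and
stacking of the PPG with its first and second central-difference
derivatives (blood-volume-change velocity and acceleration) into a
3-channel model input.

Normalization parameters are estimated per signal during training; at
test time the *averages* of the training-set parameters are applied to
every signal, so the inference path needs only the stored global
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

DEFAULT_FS = 125.0
DEFAULT_BAND = (0.5, 8.0)
DEFAULT_ORDER = 3


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class NormParams:
    """Per-signal z-score parameters (population standard deviation)."""

    mu: float
    sigma: float


@dataclass(frozen=True)
class GlobalNormParams:
    """Training-set averages of per-signal normalization parameters.

    Applied to every signal at test time; must be fit on training data
    only.
    """

    mu_bar: float
    sigma_bar: float


@dataclass
class AlignmentResult:
    """Estimated PPG-vs-ABP phase lag and the advanced PPG series.

    ``shifted_ppg`` is the PPG advanced by ``delta_t`` samples; the
    trailing ``delta_t`` samples exposed by the shift are dropped, so the
    caller must trim the ABP to the same length (`aligned_pair` does
    both).
    """

    delta_t: int
    score: float
    shifted_ppg: np.ndarray


def bandpass_filter(
    x: np.ndarray,
    fs: float = DEFAULT_FS,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass of the given order.

    Applied forward-backward (``sosfiltfilt``) so the passband waveform
    is not phase-distorted — phase lag between channels is handled
    separately by `align`, and phase distortion here would corrupt the
    derivative channels.
    """
    x = np.asarray(x, dtype=np.float64)
    if fs <= 2 * high:
        raise PreprocessError(f"fs ({fs:g} Hz) must exceed twice the upper edge")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    min_len = 3 * (2 * sos.shape[0] + 1)
    if x.size <= min_len:
        raise PreprocessError(
            f"signal too short to filter: {x.size} samples, need > {min_len}"
        )
    return sps.sosfiltfilt(sos, x)


def zscore(x: np.ndarray) -> tuple[np.ndarray, NormParams]:
    """Normalize to zero mean and unit (population) standard deviation."""
    x = np.asarray(x, dtype=np.float64)
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma < 1e-12:
        raise PreprocessError(
            "cannot z-score a constant signal (sigma = 0); such segments are "
            "quality-control failures"
        )
    return (x - mu) / sigma, NormParams(mu=mu, sigma=sigma)


def apply_norm(x: np.ndarray, params: NormParams | GlobalNormParams) -> np.ndarray:
    mu = params.mu_bar if isinstance(params, GlobalNormParams) else params.mu
    sigma = params.sigma_bar if isinstance(params, GlobalNormParams) else params.sigma
    return (np.asarray(x, dtype=np.float64) - mu) / sigma


def invert_norm(x: np.ndarray, params: NormParams | GlobalNormParams) -> np.ndarray:
    mu = params.mu_bar if isinstance(params, GlobalNormParams) else params.mu
    sigma = params.sigma_bar if isinstance(params, GlobalNormParams) else params.sigma
    return np.asarray(x, dtype=np.float64) * sigma + mu


def fit_global_norm(params: Sequence[NormParams]) -> GlobalNormParams:
    """Average per-signal normalization parameters over the training set."""
    if len(params) == 0:
        raise PreprocessError("cannot fit global normalization from an empty list")
    return GlobalNormParams(
        mu_bar=float(np.mean([p.mu for p in params])),
        sigma_bar=float(np.mean([p.sigma for p in params])),
    )


def align(ppg: np.ndarray, abp: np.ndarray, max_lag: int) -> AlignmentResult:
    """Estimate the PPG-vs-ABP phase lag by cross-correlation.

    Searches ``delta_t`` in ``[0, max_lag)`` for the maximum of the
    valid-overlap cross-correlation  ``g(Δt) = Σ_t ABP[t]·PPG[t+Δt]``,
    computed on mean-removed series (the sign and location of the peak
    are then insensitive to the ABP's positive offset).  The PPG is
    advanced by the estimated lag; the ABP is never shifted.
    """
    ppg = np.asarray(ppg, dtype=np.float64)
    abp = np.asarray(abp, dtype=np.float64)
    if ppg.shape != abp.shape or ppg.ndim != 1:
        raise PreprocessError("ppg and abp must be equal-length 1-D series")
    n = ppg.size
    if not 0 < max_lag < n:
        raise PreprocessError(f"max_lag must be in (0, {n}), got {max_lag}")
    p = ppg - ppg.mean()
    a = abp - abp.mean()
    if not (np.any(p) and np.any(a)):
        raise PreprocessError("alignment undefined for a zero-energy signal")
    scores = np.array([np.dot(a[: n - d], p[d:]) for d in range(max_lag)])
    delta_t = int(np.argmax(scores))
    return AlignmentResult(
        delta_t=delta_t,
        score=float(scores[delta_t]),
        shifted_ppg=ppg[delta_t:].copy(),
    )


def aligned_pair(
    ppg: np.ndarray, abp: np.ndarray, max_lag: int
) -> tuple[np.ndarray, np.ndarray, AlignmentResult]:
    """Align and trim both channels to the common post-shift length."""
    res = align(ppg, abp, max_lag)
    n = len(res.shifted_ppg)
    return res.shifted_ppg, np.asarray(abp, dtype=np.float64)[:n].copy(), res


def central_difference(x: np.ndarray, h: float) -> np.ndarray:
    """Two-point central-difference derivative, O(h²) at interior points.

    One-sided first-order differences are used at the two endpoints so
    the output has the same length as the input (the model requires
    equal-length channels).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise PreprocessError(f"need at least 3 samples, got {x.size}")
    if h <= 0:
        raise PreprocessError("step h must be > 0")
    return np.gradient(x, h, edge_order=1)


def make_feature_stack(ppg: np.ndarray, h: float = 1.0 / DEFAULT_FS) -> "FeatureStack":
    """Stack a preprocessed PPG with its velocity and acceleration channels."""
    d1 = central_difference(ppg, h)
    d2 = central_difference(d1, h)
    return FeatureStack(
        channels=np.stack([np.asarray(ppg, dtype=np.float64), d1, d2]), step_h=h
    )


@dataclass
class FeatureStack:
    """Model-ready (3, T) array ordered (ppg, dppg, sdppg)."""

    channels: np.ndarray
    step_h: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2 or self.channels.shape[0] != 3:
            raise ValueError(
                f"feature stack must have shape (3, T), got {self.channels.shape}"
            )

    @property
    def ppg(self) -> np.ndarray:
        return self.channels[0]

    def as_input(self) -> np.ndarray:
        """(T, 3) layout consumed by the sequence model."""
        return self.channels.T.copy()
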