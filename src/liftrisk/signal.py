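"""IMU signal conditioning and automatic lift segmentation.

A recording is a 6-channel time series from a single sternum-mounted IMU:
linear acceleration (ax, ay, az, m/s^2) and angular velocity (vx, vy, vz,
rad/s), with x vertical, y horizontal and z perpendicular to the sensor
plane.  One reference channel (vertical acceleration by default) is
band-pass filtered, rectified and smoothed with a Savitzky-Golay filter to
form an envelope; maximal runs of the envelope above an empirical threshold
give the per-lift Regions of Interest (ROIs), which are then applied to all
six channels.

Sample intervals are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

CHANNELS = ("ax", "ay", "az", "vx", "vy", "vz")


class ConfigurationError(ValueError):
    """Raised when a filter/segmentation configuration is unusable."""


@dataclass
class ImuRecording:
    """One subject-trial 6-channel inertial recording."""

    subject_id: str
    trial_label: str  # NO_RISK | RISK | unknown
    fs: float
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be > 0")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        lengths = {c: len(self.channels[c]) for c in CHANNELS}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        for c in CHANNELS:
            arr = np.asarray(self.channels[c], dtype=float)
            if np.isnan(arr).any():
                raise ValueError(f"channel {c} contains missing samples")
            self.channels[c] = arr

    @property
    def n_samples(self) -> int:
        return len(self.channels["ax"])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True, order=True)
class LiftROI:
    """Half-open sample interval [start, end) covering one lift."""

    start: int
    end: int
    source_channel: str = field(default="ax", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid ROI [{self.start}, {self.end})")

    def duration_s(self, fs: float) -> float:
        return (self.end - self.start) / fs


@dataclass
class SegmentConfig:
    """Parameters of the segmentation pipeline.

    ``sg_frame_mode='auto'`` replaces the fixed Savitzky-Golay frame with the
    nearest odd number of samples to ``0.4 * fs * lift_period_s``, which keeps
    the smoothing window well below the lift period at any sampling rate.
    """

    channel: str = "ax"
    low_hz: float = 1.0
    high_hz: float = 50.0
    order: int = 8
    sg_order: int = 3
    sg_frame: int = 1001
    sg_frame_mode: str = "fixed"  # fixed | auto
    lifts_per_min: float = 4.0
    alpha: float = 0.3
    min_duration_s: float = 1.0
    min_gap_s: float = 1.0
    contrast_min: float = 2.0
    expected_count: int | None = None


def bandpass(
    series: np.ndarray,
    fs: float,
    low_hz: float = 1.0,
    high_hz: float = 50.0,
    order: int = 8,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    The effective upper cutoff is ``min(high_hz, 0.45 * fs)`` so the design
    stays below the Nyquist frequency whatever the sampling rate; a clamp is
    logged.  ``order`` is the overall band-pass order (the underlying
    low/high prototype has order ``order // 2``).  Applied forward-backward
    (``sosfiltfilt``) so features and ROI boundaries are not phase-shifted.
    """
    if fs <= 0:
        raise ConfigurationError("fs must be > 0")
    high_eff = min(high_hz, 0.45 * fs)
    if high_eff <= low_hz:
        raise ConfigurationError(
            f"band-pass collapses: upper cutoff min({high_hz}, 0.45*{fs}) = "
            f"{high_eff:g} Hz <= lower cutoff {low_hz:g} Hz"
        )
    if high_eff < high_hz:
        logger.warning(
            "Nyquist clamp: upper cutoff reduced from %g to %g Hz (fs = %g Hz)",
            high_hz, high_eff, fs,
        )
    sos = sps.butter(order // 2, [low_hz, high_eff], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, dtype=float))


def envelope(
    series: np.ndarray,
    fs: float,
    sg_order: int = 3,
    sg_frame: int = 1001,
) -> np.ndarray:
    """Rectify a series and smooth it with a Savitzky-Golay filter.

    The frame must be odd and larger than the polynomial order; frames longer
    than the series are shrunk to the largest valid odd length (logged).
    """
    x = np.abs(np.asarray(series, dtype=float))
    n = len(x)
    if n < sg_order + 2:
        raise ValueError(f"series too short ({n} samples) for order-{sg_order} smoothing")
    frame = sg_frame
    if frame % 2 == 0:
        raise ValueError("sg_frame must be odd")
    if frame <= sg_order:
        raise ValueError("sg_frame must exceed sg_order")
    if frame > n:
        frame = n if n % 2 == 1 else n - 1
        logger.warning("SG frame shrunk from %d to %d samples (series length %d)",
                       sg_frame, frame, n)
    return sps.savgol_filter(x, frame, sg_order)


def _runs_above(env: np.ndarray, theta: float) -> list[tuple[int, int]]:
    above = env >= theta
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[np.diff(above.astype(np.int8))[edges] == 1] + 1)
    ends = list(edges[np.diff(above.astype(np.int8))[edges] == -1] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(env))
    return list(zip(starts, ends))


def _detect_at_alpha(
    env: np.ndarray,
    fs: float,
    alpha: float,
    min_duration_s: float,
    min_gap_s: float,
) -> list[tuple[int, int]]:
    theta = alpha * np.percentile(env, 95)
    runs = _runs_above(env, theta)
    # merge runs separated by short gaps, then discard short runs
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and (start - merged[-1][1]) < min_gap_s * fs:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return [(s, e) for s, e in merged if (e - s) >= min_duration_s * fs]


def detect_rois(
    env: np.ndarray,
    fs: float,
    alpha: float = 0.3,
    min_duration_s: float = 1.0,
    min_gap_s: float = 1.0,
    contrast_min: float = 2.0,
    expected_count: int | None = None,
    source_channel: str = "ax",
) -> list[LiftROI]:
    """Threshold an envelope into lift ROIs.

    The threshold is relative: ``theta = alpha * P95(envelope)``.  Runs above
    theta separated by less than ``min_gap_s`` are merged, runs shorter than
    ``min_duration_s`` discarded.  A contrast guard declares "no activity"
    (empty result) when P95 of the envelope is below ``contrast_min`` times
    its median, i.e. when there is no burst structure standing clear of the
    baseline — a flat envelope would otherwise sit entirely above any
    relative threshold.  With ``expected_count`` given, ``alpha`` is tuned by
    bisection on [0.05, 0.95] until the run count matches; if no alpha
    matches, the closest count wins and a warning is logged.
    """
    env = np.asarray(env, dtype=float)
    if env.size == 0 or np.ptp(env) == 0 and env.max() <= 0:
        if expected_count:
            raise ValueError("flat zero envelope: no lifts detectable")
        return []
    if np.percentile(env, 95) < contrast_min * np.median(env):
        if expected_count:
            raise ValueError(
                "envelope shows no burst structure (P95 below "
                f"{contrast_min} x median) but {expected_count} lifts expected"
            )
        logger.info("no burst structure in envelope (contrast guard); 0 ROIs")
        return []

    def detect(a: float) -> list[tuple[int, int]]:
        return _detect_at_alpha(env, fs, a, min_duration_s, min_gap_s)

    if expected_count is None:
        runs = detect(alpha)
    else:
        runs = detect(alpha)
        if len(runs) != expected_count:
            runs = _tune_alpha(detect, expected_count, alpha)
    return [LiftROI(s, e, source_channel) for s, e in runs]


def _tune_alpha(detect, expected_count: int, alpha0: float) -> list[tuple[int, int]]:
    """Bisect alpha in [0.05, 0.95] for a run count equal to expected_count.

    Run count is (weakly) decreasing in alpha over the useful range, so
    bisection applies; a coarse grid supplies the fallback when no exact
    match exists.
    """
    lo, hi = 0.05, 0.95
    n_lo, n_hi = len(detect(lo)), len(detect(hi))
    if n_lo == expected_count:
        return detect(lo)
    if n_hi == expected_count:
        return detect(hi)
    if n_lo >= expected_count >= n_hi:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            n_mid = len(detect(mid))
            if n_mid == expected_count:
                return detect(mid)
            if n_mid > expected_count:
                lo = mid
            else:
                hi = mid
    # no exact match: scan a grid and keep the closest count
    best_alpha, best_runs = alpha0, detect(alpha0)
    for a in np.linspace(0.05, 0.95, 91):
        runs = detect(a)
        if abs(len(runs) - expected_count) < abs(len(best_runs) - expected_count):
            best_alpha, best_runs = a, runs
    logger.warning(
        "ROI count tuning failed: wanted %d runs, best alpha %.3f gives %d",
        expected_count, best_alpha, len(best_runs),
    )
    return best_runs


def segment_recording(
    recording: ImuRecording,
    config: SegmentConfig | None = None,
) -> list[LiftROI]:
    """Band-pass -> rectify -> envelope -> threshold on the reference channel.

    The returned ROIs apply to all six channels of the recording.
    """
    config = config or SegmentConfig()
    if config.channel not in CHANNELS:
        raise ConfigurationError(f"unknown channel {config.channel!r}")
    x = recording.channels[config.channel]
    filtered = bandpass(x, recording.fs, config.low_hz, config.high_hz, config.order)
    frame = config.sg_frame
    if config.sg_frame_mode == "auto":
        period_s = 60.0 / config.lifts_per_min
        frame = int(round(0.4 * recording.fs * period_s))
        frame += (frame + 1) % 2  # next odd
        frame = max(frame, config.sg_order + 2 + (config.sg_order % 2))
    env = envelope(filtered, recording.fs, config.sg_order, frame)
    rois = detect_rois(
        env,
        recording.fs,
        alpha=config.alpha,
        min_duration_s=config.min_duration_s,
        min_gap_s=config.min_gap_s,
        contrast_min=config.contrast_min,
        expected_count=config.expected_count,
        source_channel=config.channel,
    )
    _check_rois(rois, recording.n_samples)
    return rois


def _check_rois(rois: list[LiftROI], n_samples: int) -> None:
    prev_end = 0
    for roi in rois:
        if roi.start < prev_end or roi.end > n_samples:
            raise AssertionError("ROIs must be sorted, disjoint and in bounds")
        prev_end = roi.end
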