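"""Per-lift feature extraction in the time and frequency domains.

For every lift ROI, 19 features are computed on each of the 6 inertial
channels, giving the 114-column feature table (19 x 2 signals x 3 axes):

time domain
    RSA   rectified signal area, sum(|x|) * dt
    PPA   peak-to-peak amplitude
    MEAN  mean of the rectified segment
    SD    standard deviation of the signed segment
    HM    harmonic mean of the signed segment (near-zero samples excluded)
    25P   25th percentile of the signed segment
    75P   75th percentile of the signed segment
    ZC    zero crossings (sign-state changes)
    CL    cumulative length, sum |x[i+1] - x[i]|
    FD    Katz waveform fractal dimension (>= 1)
    NSC   number of slope changes (sign changes of the first difference)

frequency domain (one-sided FFT power spectrum, DC excluded)
    EN    normalised spectral entropy in [0, 1]
    KU    kurtosis of the spectrum-value distribution
    SK    skewness of the spectrum-value distribution
    POW   total spectral power
    MDF   median frequency (50% cumulative power)
    MNF   mean (power-weighted) frequency
    PPS   peak of the power spectrum
    PF    peak frequency (smallest frequency on ties)

Notes on conventions, chosen once and documented in the methods note: MEAN
is computed on the rectified segment while SD and the percentiles use the
signed band-passed segment; the signed harmonic mean is numerically fragile
around zero crossings and is reported with |x| < 1e-12 samples excluded;
KU/SK are moments of the distribution of spectrum *values* (an alternative
spectral-shape reading over frequency is available via ``spectral_shape``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .signal import CHANNELS, ImuRecording, LiftROI

TIME_FEATURES = ("RSA", "PPA", "MEAN", "SD", "HM", "25P", "75P", "ZC", "CL", "FD", "NSC")
FREQ_FEATURES = ("EN", "KU", "SK", "POW", "MDF", "MNF", "PPS", "PF")
ALL_FEATURES = TIME_FEATURES + FREQ_FEATURES

ID_COLUMNS = ("subject", "trial", "lift_index", "label")

_HM_EPS = 1e-12
_MIN_TIME_SAMPLES = 8
_MIN_FREQ_SAMPLES = 16


def feature_columns() -> list[str]:
    """The 114 feature column names in catalogue order (feature-major)."""
    return [f"{feat}{ch}" for feat in ALL_FEATURES for ch in CHANNELS]


def zero_crossings(x: np.ndarray) -> int:
    """Count changes of sign state (-, 0, +) between consecutive samples."""
    s = np.sign(x)
    return int(np.count_nonzero(s[1:] != s[:-1]))


def katz_fd(x: np.ndarray) -> float:
    """Katz waveform fractal dimension on the (sample index, value) path.

    FD = log10(n) / (log10(n) + log10(d / L)) with L the path length, d the
    maximal distance from the first point and n the number of steps.
    Degenerate paths return 1.0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x) - 1
    if n < 1:
        return 1.0
    dx = np.diff(x)
    path = np.sqrt(1.0 + dx * dx).sum()
    idx = np.arange(len(x), dtype=float)
    d = np.sqrt(idx**2 + (x - x[0]) ** 2).max()
    if path <= 0 or d <= 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(d / path)))


def time_features(segment: np.ndarray, fs: float) -> dict[str, float]:
    """The 11 time-domain features of one ROI segment."""
    x = np.asarray(segment, dtype=float)
    if len(x) < _MIN_TIME_SAMPLES:
        raise ValueError(f"segment too short for time features: {len(x)} samples")
    dt = 1.0 / fs
    absx = np.abs(x)
    nonzero = x[absx >= _HM_EPS]
    if len(nonzero) and abs(np.sum(1.0 / nonzero)) > 0:
        hm = len(nonzero) / np.sum(1.0 / nonzero)
    else:
        hm = 0.0
    return {
        "RSA": float(absx.sum() * dt),
        "PPA": float(np.ptp(x)),
        "MEAN": float(absx.mean()),
        "SD": float(np.std(x, ddof=1)),
        "HM": float(hm),
        "25P": float(np.percentile(x, 25)),
        "75P": float(np.percentile(x, 75)),
        "ZC": float(zero_crossings(x)),
        "CL": float(np.abs(np.diff(x)).sum()),
        "FD": katz_fd(x),
        "NSC": float(zero_crossings(np.diff(x))),
    }


def power_spectrum(segment: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT power spectrum with the DC bin excluded.

    Scaled so a unit-amplitude sinusoid at a bin frequency carries total
    power 1/2 (amplitude-squared/2 convention); no window is applied.
    """
    x = np.asarray(segment, dtype=float)
    n = len(x)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    power = 2.0 * np.abs(spec) ** 2 / n**2
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not doubled
    return freqs[1:], power[1:]


def spectrum_features(freqs: np.ndarray, power: np.ndarray) -> dict[str, float]:
    """The 8 frequency-domain features from a precomputed spectrum."""
    total = float(power.sum())
    if total <= 0:
        return {"EN": 0.0, "KU": 0.0, "SK": 0.0, "POW": 0.0,
                "MDF": 0.0, "MNF": 0.0, "PPS": 0.0, "PF": 0.0}
    p = power / total
    nz = p[p > 0]
    k = len(power)
    entropy = float(-(nz * np.log(nz)).sum() / np.log(k)) if k > 1 else 0.0
    cum = np.cumsum(power)
    mdf_idx = int(np.searchsorted(cum, 0.5 * total))
    pf_idx = int(np.argmax(power))
    with warnings.catch_warnings():
        # near-constant spectra trigger scipy's precision-loss warning; the
        # degenerate moments are still the defined values here
        warnings.simplefilter("ignore", RuntimeWarning)
        ku = float(stats.kurtosis(power, fisher=False))
        sk = float(stats.skew(power))
    return {
        "EN": entropy,
        "KU": ku,
        "SK": sk,
        "POW": total,
        "MDF": float(freqs[mdf_idx]),
        "MNF": float((freqs * p).sum()),
        "PPS": float(power.max()),
        "PF": float(freqs[pf_idx]),
    }


def freq_features(segment: np.ndarray, fs: float) -> dict[str, float]:
    """The 8 frequency-domain features of one ROI segment."""
    x = np.asarray(segment, dtype=float)
    if len(x) < _MIN_FREQ_SAMPLES:
        raise ValueError(f"segment too short for frequency features: {len(x)} samples")
    freqs, power = power_spectrum(x, fs)
    return spectrum_features(freqs, power)


def spectral_shape(freqs: np.ndarray, power: np.ndarray) -> dict[str, float]:
    """Alternative KU/SK reading: moments of the spectral shape over frequency."""
    total = power.sum()
    if total <= 0:
        return {"KU": 0.0, "SK": 0.0}
    p = power / total
    mu = (freqs * p).sum()
    var = ((freqs - mu) ** 2 * p).sum()
    if var <= 0:
        return {"KU": 0.0, "SK": 0.0}
    sk = (((freqs - mu) ** 3) * p).sum() / var**1.5
    ku = (((freqs - mu) ** 4) * p).sum() / var**2
    return {"KU": float(ku), "SK": float(sk)}


def segment_features(segment: np.ndarray, fs: float) -> dict[str, float]:
    out = time_features(segment, fs)
    out.update(freq_features(segment, fs))
    return out


def build_feature_table(
    recordings: list[ImuRecording],
    rois: dict[str, list[LiftROI]] | list[list[LiftROI]],
    filtered: dict[str, dict[str, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Assemble the per-lift feature table.

    ``rois`` maps ``(subject_id, trial_label)`` keys — or parallels the
    recording list — to the lift ROIs of that recording.  ``filtered``
    optionally supplies band-pass-filtered channels keyed the same way;
    otherwise raw channel data is used.  One row per ROI; columns are the
    identifiers, the class label and the 114 features in catalogue order.
    """
    if isinstance(rois, list):
        if len(rois) != len(recordings):
            raise ValueError("one ROI list per recording required")
        roi_map = {_key(r): roi_list for r, roi_list in zip(recordings, rois)}
    else:
        roi_map = rois
    rows = []
    for rec in recordings:
        key = _key(rec)
        if key not in roi_map:
            raise ValueError(f"no ROIs supplied for recording {key}")
        data = filtered[key] if filtered is not None else rec.channels
        for lift_index, roi in enumerate(roi_map[key]):
            if roi.end > rec.n_samples:
                raise ValueError(f"ROI {roi} exceeds recording {key}")
            row: dict[str, object] = {
                "subject": rec.subject_id,
                "trial": rec.trial_label,
                "lift_index": lift_index,
                "label": rec.trial_label,
            }
            for ch in CHANNELS:
                seg = data[ch][roi.start:roi.end]
                try:
                    feats = segment_features(seg, rec.fs)
                except ValueError as exc:
                    raise ValueError(f"ROI {roi} on {key}/{ch}: {exc}") from exc
                for name, value in feats.items():
                    row[f"{name}{ch}"] = value
            rows.append(row)
    columns = list(ID_COLUMNS) + feature_columns()
    table = pd.DataFrame(rows, columns=columns)
    return table


def _key(rec: ImuRecording) -> tuple[str, str]:
    return (rec.subject_id, rec.trial_label)
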