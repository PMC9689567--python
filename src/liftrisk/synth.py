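"""Synthetic rhythmic-lifting IMU sessions with ground truth.

The generator emulates the study design this package targets: each subject
performs two 5-minute trials of 20 rhythmic lifts at 4 lifts/min, one under
an acceptable load (NO_RISK) and one under an excessive load (RISK), with a
single IMU on the sternum.  Each lift appears on every channel as a
Hann-windowed oscillatory burst (1-4 Hz content, 3-5 s long) centred in its
15 s metronome slot, on top of Gaussian sensor noise.  The two classes are
distinguished by amplitude only: RISK bursts are scaled by a class gain
``gamma`` on all channels, reproducing the direction of the real effects
(larger signal area, variability and spectral power under load) without
attempting a biomechanical forward model.

Inter-subject variability is a lognormal scale on burst amplitude; per-lift
amplitude jitter and a small timing (phase) jitter add within-trial
variability.  Everything is driven by a single seed through
``numpy.random.SeedSequence`` so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal import CHANNELS, ImuRecording, LiftROI

# per-channel burst amplitudes (m/s^2 for a*, rad/s for v*); relative sizes
# follow the qualitative ordering of the study's channel statistics
DEFAULT_AMPLITUDES = {
    "ax": 2.0, "ay": 0.7, "az": 1.2,
    "vx": 0.25, "vy": 0.6, "vz": 0.18,
}

# per-channel exponents on the class gain: the load effect is strongest on
# the z axes and weakest on vertical acceleration (ratios of the published
# class means); the RISK amplitude on channel c is scaled by gamma**exp[c]
DEFAULT_AMP_EXPONENTS = {
    "ax": 0.5, "ay": 0.9, "az": 1.1,
    "vx": 0.75, "vy": 0.8, "vz": 1.05,
}


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic cohort."""

    n_subjects: int = 13
    n_lifts: int = 20
    lifts_per_min: float = 4.0
    trial_duration_s: float = 300.0
    fs: float = 128.0
    burst_band_hz: tuple[float, float] = (1.0, 4.0)
    burst_duration_s: tuple[float, float] = (3.0, 5.0)
    noise_sd: float = 0.05
    class_gain: float = 1.2
    subject_sigma: float = 0.20
    lift_jitter_sigma: float = 0.10
    channel_jitter_sigma: float = 0.10
    timing_jitter_s: float = 0.25
    freq_exponent: float = 0.6  # burst frequencies scale by gamma**freq_exponent
    amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    amp_exponents: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMP_EXPONENTS)
    )

    def __post_init__(self) -> None:
        if self.class_gain <= 0:
            raise ValueError("class_gain must be > 0")
        period = 60.0 / self.lifts_per_min
        if self.n_lifts * period > self.trial_duration_s + 1e-9:
            raise ValueError("n_lifts do not fit in trial_duration_s at this rate")
        band_top = self.burst_band_hz[1] * max(self.class_gain, 1.0) ** self.freq_exponent
        if self.fs <= 2.0 * band_top:
            raise ValueError("fs must exceed twice the burst band top")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    amplitude_scale: float  # lognormal inter-subject factor


def make_profile(subject_id: str, config: SynthConfig, rng: np.random.Generator) -> SubjectProfile:
    scale = float(rng.lognormal(mean=0.0, sigma=config.subject_sigma))
    return SubjectProfile(subject_id=subject_id, amplitude_scale=scale)


def generate_session(
    profile: SubjectProfile,
    class_label: str,
    config: SynthConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[ImuRecording, list[LiftROI]]:
    """One trial: a 6-channel recording plus ground-truth lift ROIs.

    Deterministic for a fixed seed.  Bursts are centred at
    ``(i + 0.5) * 60 / lifts_per_min`` (plus timing jitter); the ground-truth
    ROI of a lift is its burst support, identical across channels.
    """
    if class_label not in ("NO_RISK", "RISK"):
        raise ValueError(f"class_label must be NO_RISK or RISK, got {class_label!r}")
    rng = np.random.default_rng(seed)
    n = int(round(config.trial_duration_s * config.fs))
    gamma = config.class_gain if class_label == "RISK" else 1.0
    freq_gain = gamma ** config.freq_exponent
    period = 60.0 / config.lifts_per_min
    t = np.arange(n) / config.fs

    data = {ch: rng.normal(0.0, config.noise_sd, size=n) for ch in CHANNELS}
    rois: list[LiftROI] = []
    for i in range(config.n_lifts):
        center = (i + 0.5) * period + rng.normal(0.0, config.timing_jitter_s)
        duration = rng.uniform(*config.burst_duration_s)
        half = duration / 2.0
        start = max(int(np.ceil((center - half) * config.fs)), 0)
        end = min(int(np.floor((center + half) * config.fs)) + 1, n)
        if end - start < 2:
            raise ValueError("burst fell outside the recording")
        window = np.hanning(end - start)
        lift_jitter = rng.lognormal(0.0, config.lift_jitter_sigma)
        for ch in CHANNELS:
            f = rng.uniform(*config.burst_band_hz) * freq_gain
            phase = rng.uniform(0.0, 2.0 * np.pi)
            gain = gamma ** config.amp_exponents[ch]
            ch_jitter = rng.lognormal(0.0, config.channel_jitter_sigma)
            amp = (config.amplitudes[ch] * profile.amplitude_scale
                   * lift_jitter * ch_jitter * gain)
            burst = amp * np.sin(2.0 * np.pi * f * (t[start:end] - center) + phase)
            data[ch][start:end] += window * burst
        rois.append(LiftROI(start, end))
    recording = ImuRecording(
        subject_id=profile.subject_id,
        trial_label=class_label,
        fs=config.fs,
        channels=data,
    )
    return recording, rois


def generate_cohort(
    config: SynthConfig | None = None,
    seed: int = 0,
) -> tuple[list[ImuRecording], pd.DataFrame]:
    """The full cohort: n_subjects x 2 trials (NO_RISK then RISK each).

    Returns the recordings and a ground-truth table with one row per lift:
    ``subject, trial, lift_index, start, end`` (sample indices).  With the
    default design this is 13 x 2 x 20 = 520 lift instances.
    """
    config = config or SynthConfig()
    root = np.random.SeedSequence(seed)
    profile_seq, *trial_seqs = root.spawn(1 + 2 * config.n_subjects)
    profile_rng = np.random.default_rng(profile_seq)
    recordings: list[ImuRecording] = []
    truth_rows = []
    for s in range(config.n_subjects):
        profile = make_profile(f"S{s + 1:02d}", config, profile_rng)
        for t_idx, label in enumerate(("NO_RISK", "RISK")):
            rec, rois = generate_session(
                profile, label, config, trial_seqs[2 * s + t_idx]
            )
            recordings.append(rec)
            for lift_index, roi in enumerate(rois):
                truth_rows.append({
                    "subject": profile.subject_id,
                    "trial": label,
                    "lift_index": lift_index,
                    "start": roi.start,
                    "end": roi.end,
                })
    truth = pd.DataFrame(
        truth_rows, columns=["subject", "trial", "lift_index", "start", "end"]
    )
    return recordings, truth


def truth_rois(truth: pd.DataFrame, subject: str, trial: str) -> list[LiftROI]:
    """Ground-truth ROIs of one recording from a cohort truth table."""
    sub = truth[(truth["subject"] == subject) & (truth["trial"] == trial)]
    return [LiftROI(int(r.start), int(r.end)) for r in sub.itertuples()]


def with_gain(config: SynthConfig, gamma: float) -> SynthConfig:
    return replace(config, class_gain=gamma)
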