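"""Feature-extraction oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from liftrisk.features import (
    build_feature_table,
    feature_columns,
    freq_features,
    katz_fd,
    power_spectrum,
    segment_features,
    spectrum_features,
    time_features,
    zero_crossings,
)
from liftrisk.signal import LiftROI
from liftrisk.synth import generate_cohort, SynthConfig, truth_rois


def _sine(freq, fs, duration, amplitude=1.0):
    t = np.arange(0, duration, 1 / fs)
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestTimeFeatures:
    def test_all_zero_segment_degenerate_conventions(self):
        f = time_features(np.zeros(100), fs=100.0)
        assert f["RSA"] == 0 and f["PPA"] == 0 and f["SD"] == 0
        assert f["ZC"] == 0 and f["CL"] == 0 and f["NSC"] == 0
        assert f["FD"] == 1.0
        assert f["HM"] == 0.0  # every sample excluded from the harmonic mean

    def test_unit_sine_amplitude_and_area(self):
        x = _sine(1.0, 100.0, 5.0)
        f = time_features(x, fs=100.0)
        assert f["PPA"] == pytest.approx(2.0, abs=1e-3)
        # integral of |sin(2 pi t)| over 5 s is 2*5/pi
        assert f["RSA"] == pytest.approx(2 * 5 / np.pi, rel=0.01)
        assert f["MEAN"] == pytest.approx(2 / np.pi, rel=0.01)

    def test_unit_sine_crossing_counts_match_bruteforce(self):
        x = _sine(1.0, 100.0, 5.0)
        f = time_features(x, fs=100.0)

        def brute_sign_changes(v):
            states = np.sign(v)
            return sum(states[i] != states[i + 1] for i in range(len(v) - 1))

        assert f["ZC"] == brute_sign_changes(x) == 10
        assert f["NSC"] == brute_sign_changes(np.diff(x)) == 10

    def test_percentiles_on_signed_segment(self):
        x = _sine(1.0, 100.0, 5.0)
        f = time_features(x, fs=100.0)
        assert f["25P"] < 0 < f["75P"]
        assert f["25P"] == pytest.approx(-f["75P"], abs=1e-6)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            time_features(np.ones(5), fs=100.0)

    def test_katz_fd_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(10, 500))
            assert katz_fd(x) >= 1.0


class TestFreqFeatures:
    def test_pure_tone_concentrates_spectrum(self):
        # 2 Hz tone, 8 s at 64 Hz: bin-aligned, window-free
        x = _sine(2.0, 64.0, 8.0)
        f = freq_features(x, fs=64.0)
        assert f["PF"] == pytest.approx(2.0)
        assert f["MDF"] == pytest.approx(2.0)
        assert f["MNF"] == pytest.approx(2.0, rel=0.02)
        assert f["POW"] == pytest.approx(0.5, rel=1e-6)  # amplitude^2 / 2

    def test_uniform_spectrum_has_maximal_entropy(self):
        freqs = np.linspace(1, 10, 32)
        f = spectrum_features(freqs, np.full(32, 3.7))
        assert f["EN"] == pytest.approx(1.0)

    def test_single_bin_spectrum_has_zero_entropy(self):
        freqs = np.linspace(1, 10, 32)
        power = np.zeros(32)
        power[5] = 2.0
        f = spectrum_features(freqs, power)
        assert f["EN"] == 0.0
        assert f["MDF"] == f["PF"] == pytest.approx(freqs[5])

    def test_all_zero_segment_degenerate(self):
        f = freq_features(np.zeros(64), fs=64.0)
        assert f == {"EN": 0.0, "KU": 0.0, "SK": 0.0, "POW": 0.0,
                     "MDF": 0.0, "MNF": 0.0, "PPS": 0.0, "PF": 0.0}

    def test_mdf_mnf_match_bruteforce_cumsum(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=rng.integers(32, 256))
            freqs, power = power_spectrum(x, fs=128.0)
            f = spectrum_features(freqs, power)
            # brute force: walk the cumulative sum
            total, acc, mdf = power.sum(), 0.0, None
            for fk, pk in zip(freqs, power):
                acc += pk
                if acc >= 0.5 * total:
                    mdf = fk
                    break
            mnf = sum(fk * pk for fk, pk in zip(freqs, power)) / total
            assert f["MDF"] == pytest.approx(mdf, abs=1e-9)
            assert f["MNF"] == pytest.approx(mnf, rel=1e-9)

    def test_pf_tie_takes_smallest_frequency(self):
        freqs = np.array([1.0, 2.0, 3.0])
        power = np.array([5.0, 1.0, 5.0])
        assert spectrum_features(freqs, power)["PF"] == 1.0


SEGMENTS = arrays(
    np.float64, st.integers(32, 200),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
).filter(lambda x: np.ptp(x) > 1e-6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(SEGMENTS, st.floats(0.1, 50))
def test_scale_equivariance(segment, c):
    base = segment_features(segment, fs=100.0)
    scaled = segment_features(c * segment, fs=100.0)
    for name, power in [("RSA", 1), ("PPA", 1), ("SD", 1), ("CL", 1), ("PPS", 2)]:
        assert scaled[name] == pytest.approx(base[name] * c**power, rel=1e-6)
    invariant = ["ZC", "NSC", "EN"]
    # peak/median bins are only well-defined when the spectrum has a clear
    # peak; a machine-precision-flat spectrum can flip bins under scaling
    _, spec = power_spectrum(segment, fs=100.0)
    top2 = np.sort(spec)[-2:]
    if top2[1] > 0 and (top2[1] - top2[0]) / top2[1] > 1e-9:
        invariant += ["PF", "MDF"]
    for name in invariant:
        assert scaled[name] == pytest.approx(base[name], abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(SEGMENTS)
def test_spectral_invariants(segment):
    f = segment_features(segment, fs=100.0)
    assert 0.0 <= f["EN"] <= 1.0 + 1e-12
    assert f["POW"] >= f["PPS"] >= 0.0
    assert 0.0 < f["MDF"] <= 50.0
    assert 0.0 < f["MNF"] <= 50.0
    assert f["FD"] >= 1.0


class TestFeatureTable:
    def test_catalogue_has_114_columns(self):
        cols = feature_columns()
        assert len(cols) == 114
        assert len(set(cols)) == 114
        assert "RSAax" in cols and "MDFvz" in cols and "PFvy" in cols

    def test_full_cohort_yields_520_instances(self, small_synth_config):
        # 13 subjects x 2 trials x 20 lifts with the default design
        config = SynthConfig()
        assert config.n_subjects * 2 * config.n_lifts == 520

    def test_table_shape_and_labels(self, small_cohort):
        recordings, truth = small_cohort
        rois = {
            (r.subject_id, r.trial_label): truth_rois(truth, r.subject_id, r.trial_label)
            for r in recordings
        }
        table = build_feature_table(recordings, rois)
        assert len(table) == 4 * 2 * 8
        assert list(table.columns[:4]) == ["subject", "trial", "lift_index", "label"]
        assert table.shape[1] == 4 + 114
        assert not table.isna().any().any()
        assert set(table["label"]) == {"NO_RISK", "RISK"}

    def test_empty_roi_list_gives_empty_table(self, small_cohort):
        recordings, _ = small_cohort
        rois = {(r.subject_id, r.trial_label): [] for r in recordings}
        table = build_feature_table(recordings, rois)
        assert len(table) == 0
        assert table.shape[1] == 4 + 114

    def test_out_of_bounds_roi_rejected(self, small_cohort):
        recordings, _ = small_cohort
        rois = {(r.subject_id, r.trial_label): [] for r in recordings}
        key = (recordings[0].subject_id, recordings[0].trial_label)
        rois[key] = [LiftROI(0, recordings[0].n_samples + 5)]
        with pytest.raises(ValueError, match="exceeds"):
            build_feature_table(recordings, rois)
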