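"""Filtering, resampling, windowing and the target-outlier rule."""

import numpy as np
import pytest
from scipy import signal as sps

from cufflessbp.preprocess import (
    DEFAULT_FILTERS,
    FilterSpec,
    WindowedDataset,
    bandpass,
    butter_sos,
    outlier_band,
    preprocess_recording,
    remove_outlier_targets,
    resample_record,
    segment,
)
from cufflessbp.synth import Recording, SynthConfig, generate_recording


def _recording(duration=10.0, fs=1000.0, beats=None):
    n = int(duration * fs)
    t = np.arange(n) / fs
    if beats is None:
        bt = np.arange(0.5, duration - 0.5, 1.0)
        beats = np.column_stack([bt, 120 + 0 * bt, 80 + 0 * bt])
    return Recording(channels={"ecg": np.sin(2 * np.pi * 10 * t),
                               "ppg": np.cos(2 * np.pi * 2 * t),
                               "bcg": np.sin(2 * np.pi * 8 * t)},
                     fs=fs, bp_beats=beats)


class TestBandpass:
    def test_dc_is_rejected(self):
        x = np.full(8000, 5.0)
        y = bandpass(x, 1000.0, DEFAULT_FILTERS["ecg"])
        mid = y[2000:-2000]  # past the edge transient
        assert np.max(np.abs(mid)) <= 1e-3 * 5.0

    def test_midband_gain_matches_design_response(self):
        """A tone at the PPG filter's geometric mid-band passes with the
        gain predicted by the designed transfer function (|H|^2 because the
        filter is applied forward and backward)."""
        spec = DEFAULT_FILTERS["ppg"]
        f0 = np.sqrt(spec.hpf_hz * spec.lpf_hz)  # ~2.74 Hz
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = bandpass(x, fs, spec)
        measured = np.max(np.abs(y[len(y) // 4: -len(y) // 4]))
        sos = butter_sos(spec, fs)
        _, h = sps.sosfreqz(sos, worN=[f0], fs=fs)
        expected = np.abs(h[0]) ** 2
        assert measured == pytest.approx(expected, rel=0.01)
        assert 0.95 <= measured <= 1.05

    @pytest.mark.parametrize("spec", list(DEFAULT_FILTERS.values()),
                             ids=lambda s: s.channel)
    def test_single_pass_cutoff_gain_is_minus_3db(self, spec):
        sos = butter_sos(spec, 1000.0)
        _, h = sps.sosfreqz(sos, worN=[spec.hpf_hz, spec.lpf_hz], fs=1000.0)
        gains_db = 20 * np.log10(np.abs(h))
        assert np.all(np.abs(gains_db - (-3.0103)) < 0.2)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(1000), 20.0, DEFAULT_FILTERS["ecg"])

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            bandpass(np.zeros(10), 1000.0, DEFAULT_FILTERS["ecg"])


class TestResample:
    def test_five_seconds_at_1khz_becomes_625_samples(self):
        rec = _recording(duration=5.0)
        out = resample_record(rec, 125.0)
        assert all(len(v) == 625 for v in out.channels.values())

    def test_identity_when_rates_match(self):
        rec = _recording()
        out = resample_record(rec, 1000.0)
        np.testing.assert_array_equal(out.channels["ecg"], rec.channels["ecg"])

    def test_tone_amplitude_preserved(self):
        """A 10 Hz tone survives 1000 -> 125 Hz with <2% amplitude error
        (FFT-peak oracle)."""
        rec = _recording(duration=8.0)
        out = resample_record(rec, 125.0)
        y = out.channels["ecg"]
        spec = np.abs(np.fft.rfft(y)) / len(y) * 2
        freqs = np.fft.rfftfreq(len(y), 1 / 125.0)
        k = np.argmax(spec)
        assert freqs[k] == pytest.approx(10.0, abs=freqs[1])
        assert spec[k] == pytest.approx(1.0, rel=0.02)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample_record(_recording(), 2000.0)

    def test_annotations_carry_over_unchanged(self):
        rec = _recording()
        out = resample_record(rec, 125.0)
        np.testing.assert_array_equal(out.bp_beats, rec.bp_beats)


class TestSegment:
    def test_window_count_10s_stride_1(self):
        ds = segment(_recording(10.0), stride_s=1.0)
        assert len(ds) == 6

    def test_window_count_10s_stride_8ms_at_125hz(self):
        rec = resample_record(_recording(10.0), 125.0)
        ds = segment(rec, stride_s=0.008)
        assert len(ds) == 626

    def test_every_segment_has_625_samples_at_125hz(self):
        rec = resample_record(_recording(12.0), 125.0)
        ds = segment(rec, stride_s=0.05)
        assert ds.X.shape[1:] == (625, 3)

    @pytest.mark.parametrize("T,stride", [(10.0, 0.25), (17.3, 0.7),
                                          (23.0, 1.9), (11.5, 0.013)])
    def test_count_matches_brute_force_enumeration(self, T, stride):
        fs = 125.0
        rec = resample_record(_recording(T), fs)
        ds = segment(rec, stride_s=stride)
        n = rec.n_samples
        nwin = 625
        # brute force: enumerate candidate starts directly
        count = 0
        k = 0
        while int(round(k * stride * fs)) + nwin <= n:
            count += 1
            k += 1
        assert len(ds) == count

    def test_target_is_annotation_in_force_at_window_end(self):
        bt = np.array([[0.5, 100.0, 60.0], [6.0, 130.0, 85.0]])
        rec = _recording(10.0, beats=bt)
        ds = segment(rec, stride_s=1.0)
        # windows end at ~5, 6, ... 10 s; ends >= 6 s pick the second beat
        assert ds.y_sbp[0] == 100.0
        assert np.all(ds.y_sbp[ds.t_end >= 6.0] == 130.0)

    def test_windows_before_first_annotation_are_dropped(self):
        bt = np.array([[8.0, 120.0, 80.0]])
        rec = _recording(10.0, beats=bt)
        ds = segment(rec, stride_s=1.0)
        assert np.all(ds.t_end >= 8.0)

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            segment(_recording(4.0))


def _dataset(y_sbp, y_dbp=None):
    n = len(y_sbp)
    if y_dbp is None:
        y_dbp = np.full(n, 70.0)
    return WindowedDataset(np.zeros((n, 10, 1)), np.asarray(y_sbp, float),
                           np.asarray(y_dbp, float), np.arange(n, dtype=float),
                           np.full(n, "s0", dtype="U32"), ["ecg"], 125.0)


class TestOutlierRule:
    def test_identical_targets_all_kept(self):
        ds = remove_outlier_targets(_dataset(np.full(50, 120.0)))
        assert len(ds) == 50

    def test_gaussian_retention_is_95_percent(self, rng):
        y = 115.0 + 10.0 * rng.standard_normal(100_000)
        ds = remove_outlier_targets(_dataset(y))
        assert len(ds) / 100_000 == pytest.approx(0.95, abs=0.005)

    def test_band_for_published_cohort_statistics(self):
        """mean 115.04, SD 14.64 -> retention band ~[86.35, 143.73],
        matching the reported 95% interval to 0.02 mmHg."""
        lo, hi = 115.04 - 1.96 * 14.64, 115.04 + 1.96 * 14.64
        assert lo == pytest.approx(86.34, abs=0.02)
        assert hi == pytest.approx(143.74, abs=0.02)
        # the implementation computes the same band from data
        rng = np.random.default_rng(0)
        y = 115.04 + 14.64 * rng.standard_normal(400_000)
        blo, bhi = outlier_band(y)
        assert blo == pytest.approx(lo, abs=0.15)
        assert bhi == pytest.approx(hi, abs=0.15)

    def test_either_target_outside_band_drops_segment(self):
        sbp = np.r_[np.full(99, 120.0), 121.0]
        dbp = np.r_[np.full(99, 80.0), 300.0]  # DBP outlier in last segment
        ds = remove_outlier_targets(_dataset(sbp, dbp))
        assert len(ds) == 99
        assert np.all(ds.y_dbp <= 200)


def test_filter_resample_near_commutes_on_band_limited_signal():
    """Filtering then resampling agrees with resampling then filtering for
    in-band content (regression guard for the pipeline-order choice)."""
    fs = 1000.0
    t = np.arange(int(20 * fs)) / fs
    x = np.sin(2 * np.pi * 5.0 * t) + 0.5 * np.sin(2 * np.pi * 9.0 * t)
    beats = np.array([[1.0, 120.0, 80.0]])
    rec = Recording(channels={"ppg": x}, fs=fs, bp_beats=beats)
    spec = {"ppg": DEFAULT_FILTERS["ppg"]}
    a = resample_record(
        Recording(channels={"ppg": bandpass(x, fs, spec["ppg"])},
                  fs=fs, bp_beats=beats), 125.0).channels["ppg"]
    down = resample_record(rec, 125.0)
    b = bandpass(down.channels["ppg"], 125.0, spec["ppg"])
    mid = slice(200, -200)
    assert np.max(np.abs(a[mid] - b[mid])) < 0.02 * np.max(np.abs(x))


def test_full_preprocess_chain_on_synthetic_recording():
    rec, _ = generate_recording(SynthConfig(duration_s=20.0, seed=9))
    ds = preprocess_recording(rec, stride_s=0.5, subject_id="sA")
    assert ds.X.shape[1:] == (625, 3)
    assert set(ds.subject_id) == {"sA"}
    assert np.all(ds.y_sbp > ds.y_dbp)


def test_dataset_hdf5_round_trip(tmp_path):
    ds = _dataset(np.linspace(100, 140, 7))
    path = tmp_path / "ds.h5"
    ds.save(path)
    back = WindowedDataset.load(path)
    np.testing.assert_array_equal(back.X, ds.X)
    np.testing.assert_array_equal(back.y_sbp, ds.y_sbp)
    assert list(back.subject_id) == list(ds.subject_id)
    assert back.channels == ds.channels and back.fs == ds.fs


def test_standardization_gives_zero_mean_unit_sd():
    rng = np.random.default_rng(3)
    ds = _dataset(np.full(4, 120.0))
    ds.X = rng.standard_normal(ds.X.shape) * 7 + 3
    z = ds.standardized()
    np.testing.assert_allclose(z.X.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.X.std(axis=1), 1.0, atol=1e-12)
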