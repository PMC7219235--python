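"""Fiducial detection against planted truth, feature assembly, and MLR."""

import numpy as np
import pandas as pd
import pytest

from cufflessbp.baseline import (
    FeatureExtractionError,
    build_features,
    detect_dppg_peaks,
    detect_j_peaks,
    detect_r_peaks,
    extract_features,
    features_frame,
    fit_mlr,
    predict_mlr,
    BeatFeatures,
)
from cufflessbp.preprocess import filter_recording
from cufflessbp.synth import SynthConfig, generate_recording

from conftest import clean_config


def _nearest_errors(detected, truth):
    return np.array([np.min(np.abs(detected - t)) for t in truth])


@pytest.fixture(scope="module")
def clean_filtered():
    rec, gt = generate_recording(clean_config())
    return filter_recording(rec), gt


class TestRPeaks:
    def test_clean_60bpm_minute_detects_every_beat(self, clean_filtered):
        frec, gt = clean_filtered
        r = detect_r_peaks(frec.channels["ecg"], frec.fs)
        assert abs(len(r) - len(gt.r_times)) <= 1
        errs = _nearest_errors(r, gt.r_times)
        assert np.max(errs) <= 0.010  # within 10 ms of planted R times

    def test_flat_signal_detects_nothing(self):
        assert len(detect_r_peaks(np.zeros(10_000), 1000.0)) == 0

    def test_amplitude_scaling_leaves_times_unchanged(self, clean_filtered):
        frec, _ = clean_filtered
        ecg = frec.channels["ecg"]
        r1 = detect_r_peaks(ecg, frec.fs)
        r10 = detect_r_peaks(10.0 * ecg, frec.fs)
        np.testing.assert_array_equal(r1, r10)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="100"):
            detect_r_peaks(np.zeros(1000), 50.0)


class TestJPeaks:
    def test_planted_rji_180ms_recovered(self):
        rec, gt = generate_recording(clean_config(rji_mean=180.0))
        frec = filter_recording(rec)
        jt, ok = detect_j_peaks(frec.channels["bcg"], frec.fs, gt.r_times)
        assert ok.all()
        assert np.max(np.abs(jt - gt.j_times)) <= 0.004

    def test_window_past_signal_end_is_invalid(self):
        fs = 1000.0
        bcg = np.zeros(1000)
        bcg[500] = 1.0
        # second R's search window [r+110, r+250] ms exceeds the record
        jt, ok = detect_j_peaks(bcg, fs, np.array([0.30, 0.90]))
        assert not ok[1]

    def test_j_outside_window_is_flagged_invalid(self):
        """A J wave planted at R + 300 ms: the in-window argmax hugs the
        window edge and the cycle is excluded, mirroring manual rejection."""
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        r_times = np.arange(0.5, 9.0, 1.0)
        sigma = 0.015
        bcg = np.zeros_like(t)
        for i, r in enumerate(r_times):
            off = 0.300 if i == 4 else 0.180
            u = t - (r + off)
            bcg += (1 - u**2 / sigma**2) * np.exp(-0.5 * u**2 / sigma**2)
        jt, ok = detect_j_peaks(bcg, fs, r_times)
        assert not ok[4]
        assert ok[np.arange(len(r_times)) != 4].all()
        rji = jt - r_times
        assert np.nanmax(rji) <= 0.250 + 1e-9


class TestDppgPeaks:
    def test_planted_ptt_recovered_with_template_offset(self):
        rec, gt = generate_recording(clean_config(ptt_mean=250.0))
        frec = filter_recording(rec)
        dt, ok = detect_dppg_peaks(frec.channels["ppg"], frec.fs, gt.r_times)
        assert ok.all()
        ptt = dt - gt.r_times
        # planted onset delay + documented dPPG offset = 250 + 75 ms
        assert np.max(np.abs(ptt - 0.325)) <= 0.008

    def test_zeroed_cycle_is_invalid(self):
        rec, gt = generate_recording(clean_config())
        ppg = rec.channels["ppg"].copy()
        fs = rec.fs
        r = gt.r_times[5]
        a, b = int((r + 0.02) * fs), int((r + 0.75) * fs)
        ppg[a:b] = 0.0
        taper = int(0.05 * fs)  # smooth the cut edges
        ppg[a - taper:a] *= np.linspace(1, 0, taper)
        ppg[b:b + taper] *= np.linspace(0, 1, taper)
        dt, ok = detect_dppg_peaks(ppg, fs, gt.r_times)
        assert not ok[5]
        assert ok.sum() >= len(gt.r_times) - 2

    def test_uniform_shift_equivariance(self):
        rec, gt = generate_recording(clean_config())
        fs = rec.fs
        ppg = rec.channels["ppg"]
        shift = int(0.020 * fs)
        shifted = np.r_[np.zeros(shift), ppg[:-shift]]
        d0, ok0 = detect_dppg_peaks(ppg, fs, gt.r_times)
        d1, ok1 = detect_dppg_peaks(shifted, fs, gt.r_times)
        both = ok0 & ok1
        delta = d1[both] - d0[both]
        assert np.max(np.abs(delta - 0.020)) <= 0.002


class TestBuildFeatures:
    def test_interval_arithmetic(self):
        r = np.array([1.0, 1.8])
        dppg = np.array([1.250, 2.05])
        j = np.array([1.180, 1.98])
        rows, excl = build_features(r, dppg, np.array([True, True]),
                                    j, np.array([True, True]))
        assert rows[0].ptt == pytest.approx(0.250)
        assert rows[0].rri == pytest.approx(0.8)
        assert rows[0].rji == pytest.approx(0.180)

    def test_exclusion_fraction_reported(self):
        n = 100
        r = np.arange(n, dtype=float)
        dppg = r + 0.25
        j = r + 0.18
        ok = np.ones(n, dtype=bool)
        ok[:20] = False  # 20 failed fiducials; last cycle also drops
        rows, excl = build_features(r, dppg, ok, j, np.ones(n, dtype=bool))
        assert len(rows) == 79
        assert excl == pytest.approx(0.21)

    def test_no_valid_cycles_raises(self):
        r = np.array([1.0, 2.0])
        with pytest.raises(FeatureExtractionError):
            build_features(r, r + 0.2, np.array([False, False]),
                           r + 0.18, np.array([True, True]))


class TestMLR:
    @staticmethod
    def _random_features(rng, n=200):
        return features_frame([
            BeatFeatures(r_time=float(i), rri=float(rng.uniform(0.7, 1.1)),
                         ptt=float(rng.uniform(0.20, 0.30)),
                         rji=float(rng.uniform(0.15, 0.22)))
            for i in range(n)])

    def test_noiseless_linear_coupling_recovered_exactly(self, rng):
        df = self._random_features(rng)
        # sbp = 160 - 0.2 mmHg/ms * PTT(ms) = 160 - 200 mmHg/s * PTT(s)
        sbp = 160.0 - 200.0 * df["ptt"]
        dbp = 100.0 - 100.0 * df["ptt"]
        mlr = fit_mlr(df, sbp.to_numpy(), dbp.to_numpy())
        assert mlr.coef_sbp["ptt"] == pytest.approx(-200.0, abs=1e-6)
        assert mlr.coef_sbp["rri"] == pytest.approx(0.0, abs=1e-6)
        assert mlr.coef_sbp["rji"] == pytest.approx(0.0, abs=1e-6)
        assert mlr.intercept_sbp == pytest.approx(160.0, abs=1e-6)
        pred_sbp, _ = predict_mlr(mlr, df)
        np.testing.assert_allclose(pred_sbp, sbp, atol=1e-9)

    def test_constant_column_raises_rank_error(self, rng):
        df = self._random_features(rng, n=50)
        df["ptt"] = 0.25
        with pytest.raises(np.linalg.LinAlgError, match="ptt"):
            fit_mlr(df, np.ones(50) * 120, np.ones(50) * 80)

    def test_too_few_rows_rejected(self, rng):
        df = self._random_features(rng, n=3)
        with pytest.raises(ValueError, match="4"):
            fit_mlr(df, np.zeros(3), np.zeros(3))

    def test_ptt_coefficient_negative_on_default_cohort(self, default_recording):
        rec, _ = default_recording
        df, exclusion = extract_features(rec)
        mlr = fit_mlr(df)
        assert mlr.coef_sbp["ptt"] < 0
        assert mlr.coef_dbp["ptt"] < 0
        assert exclusion < 0.5

    def test_rmse_approaches_planted_noise_level(self, rng):
        """With exact features and Gaussian target noise, MLR residual RMSE
        converges to the noise SD (consistency)."""
        df = self._random_features(rng, n=4000)
        sigma = 2.5
        sbp = 160.0 - 200.0 * df["ptt"] + sigma * rng.standard_normal(len(df))
        dbp = 100.0 - 100.0 * df["ptt"] + sigma * rng.standard_normal(len(df))
        mlr = fit_mlr(df, sbp.to_numpy(), dbp.to_numpy())
        pred, _ = predict_mlr(mlr, df)
        rmse = np.sqrt(np.mean((pred - sbp) ** 2))
        assert rmse == pytest.approx(sigma, rel=0.1)


def test_detection_pipeline_scale_invariance(clean_filtered):
    frec, gt = clean_filtered
    fs = frec.fs
    r = detect_r_peaks(frec.channels["ecg"], fs)
    j1, ok1 = detect_j_peaks(frec.channels["bcg"], fs, r)
    j2, ok2 = detect_j_peaks(7.5 * frec.channels["bcg"], fs, r)
    np.testing.assert_array_equal(ok1, ok2)
    np.testing.assert_array_equal(j1[ok1], j2[ok2])
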