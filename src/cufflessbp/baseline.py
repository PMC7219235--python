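"""Interval-feature comparator: fiducial detection + multiple linear regression.

Per cardiac cycle, three timing features are extracted at the native sampling
rate:

* RRI — interval between consecutive ECG R peaks (Pan-Tompkins detection:
  band-pass, derivative, squaring, moving-window integration, adaptive
  two-level thresholding with a refractory period, then refinement to the
  local ECG maximum),
* PTT — R peak to the maximum of the PPG first derivative, searched in
  (R, R + 0.6 s] (covers physiologic transit times while preventing
  next-beat capture at heart rates >= 50 bpm),
* RJI — R peak to the BCG J peak, the highest BCG point within
  [R + 110 ms, R + 250 ms].

Cycles in which any fiducial fails a plausibility rule (window off the end of
the record, argmax pinned to a window boundary, or peak amplitude under
0.25x the median per-cycle peak — all scale-invariant rules standing in for
manual false-positive review) are excluded, and the exclusion fraction is
reported. The surviving (RRI, PTT, RJI) rows feed an ordinary-least-squares
multiple linear regression with SBP and DBP as dependent variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.linear_model import LinearRegression

__all__ = [
    "BeatFeatures",
    "MLRModel",
    "FeatureExtractionError",
    "detect_r_peaks",
    "detect_j_peaks",
    "detect_dppg_peaks",
    "build_features",
    "extract_features",
    "fit_mlr",
    "predict_mlr",
    "J_WINDOW_S",
    "DPPG_WINDOW_S",
]

J_WINDOW_S = (0.110, 0.250)   # J-peak search window after R
DPPG_WINDOW_S = 0.600         # dPPG-peak search horizon after R
REFRACTORY_S = 0.200          # QRS refractory period
MWI_WINDOW_S = 0.150          # moving-window-integration length
AMP_FLOOR_FRACTION = 0.25     # relative per-cycle peak-amplitude floor


class FeatureExtractionError(RuntimeError):
    """Raised when no valid cardiac cycle survives feature extraction."""


@dataclass
class BeatFeatures:
    """Per-cycle interval features (seconds)."""

    r_time: float
    rri: float
    ptt: float
    rji: float
    valid: bool = True


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-peak times (s) with the Pan-Tompkins stages.

    All thresholds adapt from running signal/noise peak estimates, so the
    detected times are invariant to uniform amplitude scaling. Returns an
    empty array (no exception) when nothing crosses threshold.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz for QRS detection, got {fs}")
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < fs:
        return np.array([])

    # QRS-emphasis band-pass, derivative, squaring, integration
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(1, int(round(MWI_WINDOW_S * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    if np.max(mwi) <= 0:
        return np.array([])

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return np.array([])

    # adaptive two-level thresholding over candidate peaks, in time order
    lead = mwi[: int(2 * fs)]
    spki = 0.875 * float(np.max(lead))
    npki = 0.5 * float(np.mean(lead))
    accepted = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[c] > thr:
            accepted.append(c)
            spki = 0.125 * mwi[c] + 0.875 * spki
        else:
            npki = 0.125 * mwi[c] + 0.875 * npki

    # refine to the local ECG maximum within +/- 50 ms
    half = int(round(0.050 * fs))
    peaks = []
    for c in accepted:
        a, b = max(0, c - half), min(len(ecg), c + half + 1)
        peaks.append(a + int(np.argmax(ecg[a:b])))
    peaks = np.unique(peaks)
    if len(peaks) > 1:  # enforce the refractory period after refinement
        keep = [peaks[0]]
        for p in peaks[1:]:
            if p - keep[-1] >= refractory:
                keep.append(p)
        peaks = np.asarray(keep)
    return peaks / fs


# ---------------------------------------------------------------------------
# Per-cycle fiducials with validity flags
# ---------------------------------------------------------------------------

def _relative_floor(amps: np.ndarray, ok: np.ndarray) -> float:
    vals = amps[ok & np.isfinite(amps)]
    if len(vals) == 0:
        return np.inf
    return AMP_FLOOR_FRACTION * float(np.median(vals))


def detect_j_peaks(bcg: np.ndarray, fs: float, r_times: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """BCG J peak per cycle: argmax in [R+110 ms, R+250 ms].

    Returns (times, valid). A cycle is invalid when its window runs off the
    signal, the argmax sits on a window boundary (the true peak lies
    outside), or the peak amplitude is under the relative noise floor.
    """
    bcg = np.asarray(bcg, dtype=float)
    n = len(bcg)
    times = np.full(len(r_times), np.nan)
    valid = np.zeros(len(r_times), dtype=bool)
    amps = np.full(len(r_times), np.nan)
    interior = np.zeros(len(r_times), dtype=bool)
    for i, r in enumerate(r_times):
        i0 = int(round((r + J_WINDOW_S[0]) * fs))
        i1 = int(round((r + J_WINDOW_S[1]) * fs))
        if i0 < 0 or i1 >= n:
            continue
        w = bcg[i0:i1 + 1]
        k = int(np.argmax(w))
        times[i] = (i0 + k) / fs
        amps[i] = w[k]
        interior[i] = 0 < k < len(w) - 1
    floor = _relative_floor(amps, interior)
    valid = interior & (amps >= floor)
    return times, valid


def detect_dppg_peaks(ppg: np.ndarray, fs: float, r_times: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """dPPG peak per cycle: max of the PPG first derivative in (R, R+0.6 s].

    Returns (times, valid); invalid when the window is truncated, no positive
    derivative maximum exists, the argmax is pinned to a boundary, or the
    derivative peak is under the relative floor.
    """
    ppg = np.asarray(ppg, dtype=float)
    d = np.diff(ppg) * fs  # derivative between samples i and i+1
    n = len(d)
    times = np.full(len(r_times), np.nan)
    amps = np.full(len(r_times), np.nan)
    interior = np.zeros(len(r_times), dtype=bool)
    for i, r in enumerate(r_times):
        i0 = int(np.floor(r * fs)) + 1
        i1 = int(round((r + DPPG_WINDOW_S) * fs))
        if i0 < 0 or i1 >= n:
            continue
        w = d[i0:i1 + 1]
        k = int(np.argmax(w))
        times[i] = (i0 + k + 0.5) / fs
        amps[i] = w[k]
        interior[i] = (0 < k < len(w) - 1) and w[k] > 0
    floor = _relative_floor(amps, interior)
    valid = interior & (amps >= floor)
    return times, valid


def build_features(r_times: np.ndarray,
                   dppg_times: np.ndarray, dppg_valid: np.ndarray,
                   j_times: np.ndarray, j_valid: np.ndarray
                   ) -> tuple[list[BeatFeatures], float]:
    """Assemble per-cycle (RRI, PTT, RJI) rows, excluding incomplete cycles.

    The last cycle has no following R peak and is always excluded. Returns
    the valid rows and the excluded fraction of cycles.
    """
    nb = len(r_times)
    if nb == 0:
        raise FeatureExtractionError("no R peaks: zero cardiac cycles")
    rows: list[BeatFeatures] = []
    for i in range(nb):
        has_next = i + 1 < nb
        ok = bool(has_next and dppg_valid[i] and j_valid[i])
        if not ok:
            continue
        rows.append(BeatFeatures(
            r_time=float(r_times[i]),
            rri=float(r_times[i + 1] - r_times[i]),
            ptt=float(dppg_times[i] - r_times[i]),
            rji=float(j_times[i] - r_times[i]),
        ))
    exclusion = 1.0 - len(rows) / nb
    if not rows:
        raise FeatureExtractionError(
            f"zero valid cardiac cycles out of {nb}")
    return rows, exclusion


def features_frame(rows: list[BeatFeatures],
                   sbp: np.ndarray | None = None,
                   dbp: np.ndarray | None = None) -> pd.DataFrame:
    df = pd.DataFrame([{"r_time": f.r_time, "rri": f.rri, "ptt": f.ptt,
                        "rji": f.rji} for f in rows])
    if sbp is not None:
        df["sbp"] = sbp
    if dbp is not None:
        df["dbp"] = dbp
    return df


def extract_features(rec, prefiltered: bool = False) -> tuple[pd.DataFrame, float]:
    """Full fiducial pipeline on a Recording at its native rate.

    Returns a frame with columns r_time, rri, ptt, rji, sbp, dbp (targets are
    the beat annotation in force at each R time) and the cycle-exclusion
    fraction. Set ``prefiltered=True`` when the channels are already
    band-passed.
    """
    from .preprocess import filter_recording  # local import avoids a cycle

    if not prefiltered:
        rec = filter_recording(rec)
    fs = rec.fs
    r = detect_r_peaks(rec.channels["ecg"], fs)
    if len(r) == 0:
        raise FeatureExtractionError("no R peaks detected")
    dppg_t, dppg_ok = detect_dppg_peaks(rec.channels["ppg"], fs, r)
    j_t, j_ok = detect_j_peaks(rec.channels["bcg"], fs, r)
    rows, exclusion = build_features(r, dppg_t, dppg_ok, j_t, j_ok)
    beat_t = rec.bp_beats[:, 0]
    sbp, dbp = [], []
    for f in rows:
        k = np.searchsorted(beat_t, f.r_time + 1e-9, side="right") - 1
        k = max(k, 0)
        sbp.append(rec.bp_beats[k, 1])
        dbp.append(rec.bp_beats[k, 2])
    return features_frame(rows, np.asarray(sbp), np.asarray(dbp)), exclusion


# ---------------------------------------------------------------------------
# Multiple linear regression
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ("rri", "ptt", "rji")


@dataclass
class MLRModel:
    """OLS coefficients (mmHg per second of interval) for SBP and DBP."""

    coef_sbp: dict[str, float]
    intercept_sbp: float
    coef_dbp: dict[str, float]
    intercept_dbp: float


def _design(features: pd.DataFrame) -> np.ndarray:
    return features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)


def _check_rank(X: np.ndarray) -> None:
    bad = [c for j, c in enumerate(FEATURE_COLUMNS)
           if np.std(X[:, j]) < 1e-12]
    if bad:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: constant column(s) {bad}")
    aug = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(aug)
    if rank < aug.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {aug.shape[1]}): "
            f"collinear columns among {FEATURE_COLUMNS}")


def fit_mlr(features: pd.DataFrame, sbp: np.ndarray | None = None,
            dbp: np.ndarray | None = None) -> MLRModel:
    """Ordinary least squares of SBP and DBP on (RRI, PTT, RJI)."""
    X = _design(features)
    if len(X) < 4:
        raise ValueError(f"need >= 4 rows (3 predictors + intercept), got {len(X)}")
    _check_rank(X)
    sbp = features["sbp"].to_numpy() if sbp is None else np.asarray(sbp)
    dbp = features["dbp"].to_numpy() if dbp is None else np.asarray(dbp)
    out = []
    for y in (sbp, dbp):
        reg = LinearRegression().fit(X, y)
        out.append((dict(zip(FEATURE_COLUMNS, reg.coef_)), float(reg.intercept_)))
    (cs, is_), (cd, id_) = out
    return MLRModel(cs, is_, cd, id_)


def predict_mlr(model: MLRModel, features: pd.DataFrame
                ) -> tuple[np.ndarray, np.ndarray]:
    X = _design(features)
    sbp = model.intercept_sbp + X @ np.array(
        [model.coef_sbp[c] for c in FEATURE_COLUMNS])
    dbp = model.intercept_dbp + X @ np.array(
        [model.coef_dbp[c] for c in FEATURE_COLUMNS])
    return sbp, dbp
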