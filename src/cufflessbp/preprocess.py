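"""Preprocessing: band-pass filtering, resampling, windowing, outlier removal.

Pipeline order (at the package's choice, applied by :func:`preprocess_recording`):

1. zero-phase 2nd-order Butterworth band-pass per channel at the native rate
   (ECG 0.5-35 Hz, BCG 4-15 Hz, PPG 0.5-15 Hz),
2. resample the whole record to 125 Hz,
3. cut 5-s sliding windows whose (SBP, DBP) target is the beat annotation in
   force at the window's final sample,
4. drop windows whose targets fall outside mean +/- 1.96 SD.

Zero-phase (forward-backward) filtering is used so fiducial timings are not
skewed by group delay. The minimum window shift after the 125 Hz resample is
one sample (8 ms); `stride_s` defaults to 0.008 s accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

from .synth import Recording

__all__ = [
    "FilterSpec",
    "WindowedDataset",
    "DEFAULT_FILTERS",
    "bandpass",
    "butter_sos",
    "filter_recording",
    "resample_record",
    "segment",
    "remove_outlier_targets",
    "outlier_band",
    "preprocess_recording",
]

Z_95 = 1.96  # two-sided 95% normal quantile used by the target-outlier rule


@dataclass(frozen=True)
class FilterSpec:
    """Band edges of one channel's 2nd-order Butterworth band-pass."""

    channel: str
    hpf_hz: float
    lpf_hz: float
    order: int = 2

    def validate(self, fs: float) -> None:
        if not (0 < self.hpf_hz < self.lpf_hz):
            raise ValueError(
                f"{self.channel}: need 0 < hpf ({self.hpf_hz}) < lpf ({self.lpf_hz})")
        if self.lpf_hz >= fs / 2:
            raise ValueError(
                f"{self.channel}: lpf {self.lpf_hz} Hz >= Nyquist {fs / 2} Hz")


DEFAULT_FILTERS: dict[str, FilterSpec] = {
    "ecg": FilterSpec("ecg", 0.5, 35.0),
    "bcg": FilterSpec("bcg", 4.0, 15.0),
    "ppg": FilterSpec("ppg", 0.5, 15.0),
}


def butter_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the band-pass in second-order-section form."""
    spec.validate(fs)
    return sps.butter(spec.order, [spec.hpf_hz, spec.lpf_hz],
                      btype="bandpass", fs=fs, output="sos")


def bandpass(signal: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass; output length == input."""
    sos = butter_sos(spec, fs)
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if len(signal) <= padlen:
        raise ValueError(
            f"signal too short to filter: {len(signal)} samples <= {padlen}")
    return sps.sosfiltfilt(sos, signal)


def filter_recording(rec: Recording,
                     specs: dict[str, FilterSpec] | None = None) -> Recording:
    """Apply the per-channel band-passes to every channel of a recording."""
    specs = specs or DEFAULT_FILTERS
    out = {}
    for name, sig in rec.channels.items():
        out[name] = bandpass(sig, rec.fs, specs[name]) if name in specs else sig.copy()
    return Recording(channels=out, fs=rec.fs, bp_beats=rec.bp_beats.copy(),
                     meta={**rec.meta, "filtered": True})


def resample_record(rec: Recording, fs_target: float = 125.0) -> Recording:
    """Polyphase-resample all channels to `fs_target` (downsampling only).

    Beat annotations are timestamps, not sample indices, and carry over
    unchanged.
    """
    if fs_target > rec.fs:
        raise ValueError(
            f"upsampling not supported: fs_target {fs_target} > fs {rec.fs}")
    if fs_target == rec.fs:
        return Recording(channels={k: v.copy() for k, v in rec.channels.items()},
                         fs=rec.fs, bp_beats=rec.bp_beats.copy(), meta=dict(rec.meta))
    frac = Fraction(fs_target / rec.fs).limit_denominator(10000)
    out = {name: sps.resample_poly(sig, frac.numerator, frac.denominator)
           for name, sig in rec.channels.items()}
    return Recording(channels=out, fs=fs_target, bp_beats=rec.bp_beats.copy(),
                     meta={**rec.meta, "resampled_from": rec.fs})


@dataclass
class WindowedDataset:
    """Fixed-length input segments paired with (SBP, DBP) targets.

    ``X`` has shape (n_segments, n_samples, n_channels); targets are the BP
    annotation in force at each segment's final sample.
    """

    X: np.ndarray
    y_sbp: np.ndarray
    y_dbp: np.ndarray
    t_end: np.ndarray
    subject_id: np.ndarray
    channels: list[str]
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y_sbp) == len(self.y_dbp)
                == len(self.t_end) == len(self.subject_id)):
            raise ValueError("WindowedDataset arrays must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "WindowedDataset":
        return WindowedDataset(self.X[idx], self.y_sbp[idx], self.y_dbp[idx],
                               self.t_end[idx], self.subject_id[idx],
                               list(self.channels), self.fs)

    def select_channels(self, names: list[str]) -> "WindowedDataset":
        cols = [self.channels.index(n) for n in names]
        return WindowedDataset(self.X[:, :, cols], self.y_sbp, self.y_dbp,
                               self.t_end, self.subject_id, list(names), self.fs)

    def standardized(self) -> "WindowedDataset":
        """Per-segment, per-channel zero-mean unit-variance amplitude scaling."""
        mu = self.X.mean(axis=1, keepdims=True)
        sd = self.X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return WindowedDataset((self.X - mu) / sd, self.y_sbp, self.y_dbp,
                               self.t_end, self.subject_id,
                               list(self.channels), self.fs)

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        first = parts[0]
        return WindowedDataset(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y_sbp for p in parts]),
            np.concatenate([p.y_dbp for p in parts]),
            np.concatenate([p.t_end for p in parts]),
            np.concatenate([p.subject_id for p in parts]),
            list(first.channels), first.fs)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X)
            f.create_dataset("y_sbp", data=self.y_sbp)
            f.create_dataset("y_dbp", data=self.y_dbp)
            f.create_dataset("t_end", data=self.t_end)
            f.create_dataset("subject_id",
                             data=np.asarray(self.subject_id, dtype="S32"))
            f.attrs["channels"] = ",".join(self.channels)
            f.attrs["fs"] = self.fs

    @staticmethod
    def load(path: str | Path) -> "WindowedDataset":
        with h5py.File(path, "r") as f:
            return WindowedDataset(
                f["X"][()], f["y_sbp"][()], f["y_dbp"][()], f["t_end"][()],
                f["subject_id"][()].astype("U32"),
                f.attrs["channels"].split(","), float(f.attrs["fs"]))


def segment(rec: Recording, window_s: float = 5.0, stride_s: float = 0.008,
            subject_id: str = "s0") -> WindowedDataset:
    """Cut half-open [t, t + window_s) sliding windows advanced by `stride_s`.

    The target of each window is the beat annotation in force (sample-and-hold
    over beat times) at the window's final sample; windows ending before the
    first annotation are dropped.
    """
    if rec.duration_s < window_s:
        raise ValueError(
            f"recording ({rec.duration_s:.2f} s) shorter than one "
            f"{window_s}-s window")
    if rec.bp_beats.shape[0] == 0:
        raise ValueError("recording has no beat BP annotations")
    fs = rec.fs
    n = rec.n_samples
    nwin = int(round(window_s * fs))
    names = list(rec.channels)
    sig = np.stack([rec.channels[c] for c in names], axis=-1)  # (n, C)

    beat_t = rec.bp_beats[:, 0]
    starts = []
    k = 0
    while True:
        i0 = int(round(k * stride_s * fs))
        if i0 + nwin > n:
            break
        starts.append(i0)
        k += 1
    X, ysbp, ydbp, tend = [], [], [], []
    for i0 in starts:
        t_end = (i0 + nwin - 1) / fs
        j = np.searchsorted(beat_t, t_end, side="right") - 1
        if j < 0:
            continue  # target not yet defined
        X.append(sig[i0:i0 + nwin])
        ysbp.append(rec.bp_beats[j, 1])
        ydbp.append(rec.bp_beats[j, 2])
        tend.append(t_end)
    if not X:
        raise ValueError("no windows could be emitted (no annotation coverage)")
    nkeep = len(X)
    return WindowedDataset(np.stack(X), np.asarray(ysbp), np.asarray(ydbp),
                           np.asarray(tend),
                           np.full(nkeep, subject_id, dtype="U32"),
                           names, fs)


def outlier_band(y: np.ndarray) -> tuple[float, float]:
    """The mean +/- 1.96 SD retention band (sample SD)."""
    m = float(np.mean(y))
    sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
    return m - Z_95 * sd, m + Z_95 * sd


def remove_outlier_targets(ds: WindowedDataset) -> WindowedDataset:
    """Drop segments whose SBP *or* DBP target lies outside mean +/- 1.96 SD.

    Band statistics come from the dataset passed in; a zero-SD target series
    degenerates to "keep everything". Applied exactly once in the pipeline.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    keep = np.ones(len(ds), dtype=bool)
    for y in (ds.y_sbp, ds.y_dbp):
        lo, hi = outlier_band(y)
        if hi > lo:  # SD == 0 -> keep all
            keep &= (y >= lo) & (y <= hi)
    return ds.subset(keep)


def preprocess_recording(rec: Recording, specs: dict[str, FilterSpec] | None = None,
                         fs_target: float = 125.0, window_s: float = 5.0,
                         stride_s: float = 0.008, subject_id: str = "s0",
                         remove_outliers: bool = True) -> WindowedDataset:
    """Filter -> resample -> segment (-> outlier removal) for one recording."""
    rec = filter_recording(rec, specs)
    rec = resample_record(rec, fs_target)
    ds = segment(rec, window_s=window_s, stride_s=stride_s, subject_id=subject_id)
    if remove_outliers:
        ds = remove_outlier_targets(ds)
    return ds
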