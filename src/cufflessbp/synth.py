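"""Synthetic synchronized ECG / PPG / BCG / blood-pressure recordings.

The generator emulates a seated resting-subject acquisition: lead-II-like ECG
with sharp R waves, a finger-PPG pulse delayed from each R peak by a slowly
modulated pulse transit time (PTT), a seat-sensor BCG whose J wave follows
each R peak by an R-J interval (RJI), and a beat-to-beat SBP/DBP reference
that is *negatively* coupled to PTT:

    SBP_i = sbp_intercept + sbp_slope * PTT_i[ms] + eps_i,   sbp_slope < 0

(and likewise for DBP). Every fiducial time is recorded in a
:class:`GroundTruth` object *before* noise is injected, so peak detectors and
feature extractors can be tested against exact planted truth.

Waveform morphology is deliberately simple — only the timing and the PTT-BP
coupling are load-bearing for downstream components:

* ECG beat: a sum of Gaussians (P, Q, R, S, T lobes) centered on the R time.
* PPG pulse: raised-cosine rise over ``PPG_RISE_S`` seconds then a
  raised-cosine decay; the steepest-rising point (the dPPG-peak fiducial)
  sits exactly ``PPG_DPEAK_OFFSET_MS`` after pulse onset, so a measured
  R-to-dPPG interval equals the planted PTT plus that documented constant.
* BCG J wave: a Mexican-hat (Ricker) wavelet, positive central lobe at the
  J time.

Additive disturbances: a <=0.4 Hz baseline-wander sinusoid, a power-line
sinusoid and white Gaussian noise, each per-channel with a shared amplitude
setting. Amplitude units are arbitrary (positive-peak convention).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "Recording",
    "ConfigurationError",
    "RecordingIOError",
    "generate_recording",
    "write_recording",
    "read_recording",
    "PPG_DPEAK_OFFSET_MS",
]

#: Offset (ms) from PPG pulse onset to the maximum of its first derivative.
#: The rise is a raised cosine over PPG_RISE_S, whose derivative peaks at the
#: half-rise point.
PPG_RISE_S = 0.150
PPG_DECAY_S = 0.450
PPG_DPEAK_OFFSET_MS = 1000.0 * PPG_RISE_S / 2.0  # = 75 ms

#: Width (s) of the Ricker J wave.
BCG_J_SIGMA_S = 0.015

#: Baseline-wander frequency (Hz); kept below the 0.4 Hz spectral ceiling.
WANDER_HZ = 0.25

# ECG template lobes: (center offset s, amplitude, sigma s)
_ECG_LOBES = (
    (-0.170, 0.12, 0.025),   # P
    (-0.018, -0.12, 0.008),  # Q
    (0.000, 1.00, 0.010),    # R
    (0.018, -0.18, 0.008),   # S
    (0.280, 0.22, 0.045),    # T
)


class ConfigurationError(ValueError):
    """Raised when a SynthConfig violates one of its invariants."""


class RecordingIOError(IOError):
    """Raised on malformed or unsupported recording files."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic cardiovascular recording.

    Times are seconds, intervals milliseconds, pressures mmHg, rates bpm.
    """

    duration_s: float = 60.0
    fs: float = 1000.0
    hr_mean: float = 70.0
    hr_sd: float = 2.0
    ptt_mean: float = 250.0
    ptt_amplitude: float = 30.0
    ptt_period_s: float = 30.0
    rji_mean: float = 180.0
    rji_sd_ms: float = 5.0
    sbp_intercept: float = 160.0
    sbp_slope: float = -0.18
    dbp_intercept: float = 100.0
    dbp_slope: float = -0.12
    bp_noise_sd: float = 1.0
    noise_wander_amp: float = 0.10
    noise_powerline_amp: float = 0.02
    noise_white_sd: float = 0.02
    powerline_hz: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.duration_s < 10:
            raise ConfigurationError(
                f"duration_s must be >= 10 s (one 5-s window after warm-up), "
                f"got {self.duration_s}")
        if not (110.0 <= self.rji_mean <= 250.0):
            raise ConfigurationError(
                f"rji_mean must lie in [110, 250] ms (the J-search window), "
                f"got {self.rji_mean}")
        if self.sbp_slope >= 0:
            raise ConfigurationError(
                f"sbp_slope must be negative (PTT is negatively correlated "
                f"with BP), got {self.sbp_slope}")
        if self.dbp_slope >= 0:
            raise ConfigurationError(
                f"dbp_slope must be negative, got {self.dbp_slope}")
        if self.hr_mean <= 0:
            raise ConfigurationError(f"hr_mean must be positive, got {self.hr_mean}")
        for name in ("hr_sd", "ptt_amplitude", "ptt_period_s", "rji_sd_ms",
                     "bp_noise_sd", "noise_wander_amp", "noise_powerline_amp",
                     "noise_white_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """Planted fiducials and targets, recorded before noise injection."""

    r_times: np.ndarray          # s
    ppg_onset_times: np.ndarray  # s, pulse foot
    dppg_peak_times: np.ndarray  # s, steepest-rise fiducial
    j_times: np.ndarray          # s
    ptt_ms: np.ndarray           # planted onset delay, ms
    rji_ms: np.ndarray           # ms
    sbp_beats: np.ndarray        # mmHg
    dbp_beats: np.ndarray        # mmHg

    def __post_init__(self) -> None:
        n = len(self.r_times)
        for f in dataclasses.fields(self):
            arr = getattr(self, f.name)
            if len(arr) != n:
                raise ValueError(f"GroundTruth field {f.name} length mismatch")
        for f in ("r_times", "ppg_onset_times", "dppg_peak_times", "j_times"):
            t = getattr(self, f)
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"GroundTruth {f} must be strictly increasing")


@dataclass
class Recording:
    """Synchronized multi-channel waveforms plus per-beat BP annotations."""

    channels: dict[str, np.ndarray]
    fs: float
    bp_beats: np.ndarray  # (n, 3) columns: time s, SBP, DBP
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.bp_beats = np.atleast_2d(np.asarray(self.bp_beats, dtype=float))
        if self.bp_beats.size and self.bp_beats.shape[1] != 3:
            raise ValueError("bp_beats must have columns (time, sbp, dbp)")
        if self.bp_beats.size and np.any(self.bp_beats[:, 1] <= self.bp_beats[:, 2]):
            raise ValueError("every beat must satisfy SBP > DBP")

    @property
    def duration_s(self) -> float:
        n = len(next(iter(self.channels.values())))
        return n / self.fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


def _add_lobe(sig: np.ndarray, fs: float, center_s: float, template: np.ndarray,
              t0_offset_s: float) -> None:
    """Overlap-add a sampled template whose t=0 is `t0_offset_s` into it."""
    start = int(round((center_s - t0_offset_s) * fs))
    a = max(start, 0)
    b = min(start + len(template), len(sig))
    if b > a:
        sig[a:b] += template[a - start: b - start]


def _gauss_template(fs: float, amp: float, sigma: float) -> tuple[np.ndarray, float]:
    half = 4.0 * sigma
    t = np.arange(-half, half, 1.0 / fs)
    return amp * np.exp(-0.5 * (t / sigma) ** 2), half


def _ppg_template(fs: float) -> np.ndarray:
    """Raised-cosine rise then raised-cosine decay, onset at index 0."""
    u = np.arange(0.0, PPG_RISE_S + PPG_DECAY_S, 1.0 / fs)
    rise = u < PPG_RISE_S
    out = np.empty_like(u)
    out[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / PPG_RISE_S))
    out[~rise] = 0.5 * (1.0 + np.cos(np.pi * (u[~rise] - PPG_RISE_S) / PPG_DECAY_S))
    return out


def _ricker_template(fs: float) -> tuple[np.ndarray, float]:
    half = 4.0 * BCG_J_SIGMA_S
    t = np.arange(-half, half, 1.0 / fs)
    s2 = BCG_J_SIGMA_S**2
    return (1.0 - t**2 / s2) * np.exp(-0.5 * t**2 / s2), half


def generate_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Generate one recording with exact planted ground truth.

    Deterministic for a given config (seeded); ground truth is computed
    before noise injection, so noise amplitudes never perturb it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    # beat times: warm-up 0.5 s, stop 1 s before the end so pulses fit
    r_list: list[float] = []
    tt = 0.5
    while tt < config.duration_s - 1.0:
        r_list.append(tt)
        hr = max(30.0, config.hr_mean + config.hr_sd * rng.standard_normal())
        tt += 60.0 / hr
    r_times = np.asarray(r_list)
    nb = len(r_times)

    # planted intervals
    ptt_ms = config.ptt_mean + config.ptt_amplitude * np.sin(
        2.0 * np.pi * r_times / config.ptt_period_s)
    rji_ms = np.clip(
        config.rji_mean + config.rji_sd_ms * rng.standard_normal(nb),
        112.0, 248.0)
    sbp = (config.sbp_intercept + config.sbp_slope * ptt_ms
           + config.bp_noise_sd * rng.standard_normal(nb))
    dbp = (config.dbp_intercept + config.dbp_slope * ptt_ms
           + config.bp_noise_sd * rng.standard_normal(nb))
    onset_times = r_times + ptt_ms / 1000.0
    dppg_times = onset_times + PPG_DPEAK_OFFSET_MS / 1000.0
    j_times = r_times + rji_ms / 1000.0

    truth = GroundTruth(r_times, onset_times, dppg_times, j_times,
                        ptt_ms, rji_ms, sbp, dbp)

    ecg = np.zeros(n)
    for off, amp, sigma in _ECG_LOBES:
        tpl, half = _gauss_template(fs, amp, sigma)
        for r in r_times:
            _add_lobe(ecg, fs, r + off, tpl, half)

    ppg = np.zeros(n)
    ppg_tpl = _ppg_template(fs)
    for onset in onset_times:
        _add_lobe(ppg, fs, onset, ppg_tpl, 0.0)

    bcg = np.zeros(n)
    j_tpl, j_half = _ricker_template(fs)
    for j in j_times:
        _add_lobe(bcg, fs, j, j_tpl, j_half)

    channels = {"ecg": ecg, "ppg": ppg, "bcg": bcg}
    for sig in channels.values():
        phase_w, phase_p = rng.uniform(0, 2 * np.pi, size=2)
        sig += config.noise_wander_amp * np.sin(2 * np.pi * WANDER_HZ * t + phase_w)
        sig += config.noise_powerline_amp * np.sin(
            2 * np.pi * config.powerline_hz * t + phase_p)
        sig += config.noise_white_sd * rng.standard_normal(n)

    bp_beats = np.column_stack([r_times, sbp, dbp])
    rec = Recording(channels=channels, fs=fs, bp_beats=bp_beats,
                    meta={"generator": "cufflessbp.synth",
                          "config": dataclasses.asdict(config)})
    return rec, truth


# ---------------------------------------------------------------------------
# File I/O: CSV waveform + JSON beat-annotation sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".beats.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".beats.json")


def write_recording(rec: Recording, path: str | Path, format: str = "csv") -> Path:
    """Write a recording to disk.

    CSV layout: header ``time,<channel...>``, one row per sample, 6 decimal
    places. Beat annotations and sampling rate go to a ``<name>.beats.json``
    sidecar. EDF output is not supported in this build.
    """
    path = Path(path)
    if format != "csv":
        raise RecordingIOError(
            f"unsupported format {format!r}: only 'csv' is available")
    n = rec.n_samples
    df = pd.DataFrame({"time": np.arange(n) / rec.fs})
    for name, sig in rec.channels.items():
        df[name] = sig
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "fs": rec.fs,
        "beats": [{"t": float(tt), "sbp": float(s), "dbp": float(d)}
                  for tt, s, d in rec.bp_beats],
        "meta": rec.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_recording(path: str | Path,
                   channels: tuple[str, ...] = ("ecg", "ppg", "bcg")) -> Recording:
    """Read a CSV recording and its JSON sidecar back into a Recording."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise RecordingIOError(f"cannot parse {path}: {exc}") from exc
    if "time" not in df.columns:
        raise RecordingIOError(f"{path}: missing required column 'time'")
    for ch in channels:
        if ch not in df.columns:
            raise RecordingIOError(f"{path}: missing channel column {ch!r}")
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        side = json.loads(sidecar_file.read_text())
        fs = float(side["fs"])
        beats = np.array([[b["t"], b["sbp"], b["dbp"]] for b in side["beats"]])
        meta = side.get("meta", {})
    else:
        dt = np.median(np.diff(df["time"].to_numpy()))
        fs = 1.0 / dt
        beats = np.empty((0, 3))
        meta = {}
    if beats.size == 0:
        beats = beats.reshape(0, 3)
    return Recording(
        channels={ch: df[ch].to_numpy(dtype=float) for ch in channels},
        fs=fs, bp_beats=beats, meta=meta)
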