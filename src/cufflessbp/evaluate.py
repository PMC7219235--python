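"""Accuracy metrics and clinical validation standards for BP estimators.

* Regression metrics: RMSE, MAE, SD of absolute errors (the "MAE +/- SD"
  convention), and R^2.
* Bland-Altman limits of agreement: mean difference +/- 1.96 SD, with the
  estimate-minus-reference sign convention.
* AAMI criterion: |mean signed error| <= 5 mmHg and SD of signed errors
  <= 8 mmHg (boundary inclusive); the 85-subject population requirement is
  reported as a warning flag, not a failure.
* BHS grading: cumulative fractions of absolute errors within 5/10/15 mmHg,
  graded A (60/85/95), B (50/75/90), C (40/65/80), else D; thresholds
  inclusive.
* Attention-section arithmetic: the 8 Bi-GRU timesteps of a 625-sample,
  125 Hz window map back to seven 81-sample (648 ms) sections and one
  58-sample (464 ms) tail section, with per-section mean attention weight
  and distance from the window end (the target time).

All standard deviations are sample SDs (ddof = 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EvalReport",
    "AttentionSectionMap",
    "regression_metrics",
    "bland_altman",
    "aami_check",
    "bhs_grade",
    "attention_sections",
    "evaluate_predictions",
    "BHS_THRESHOLDS",
    "AAMI_MEAN_LIMIT",
    "AAMI_SD_LIMIT",
    "AAMI_MIN_SUBJECTS",
]

AAMI_MEAN_LIMIT = 5.0   # mmHg
AAMI_SD_LIMIT = 8.0     # mmHg
AAMI_MIN_SUBJECTS = 85

# grade -> (pct within 5, within 10, within 15) minima
BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0),
                  "B": (50.0, 75.0, 90.0),
                  "C": (40.0, 65.0, 80.0)}


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def regression_metrics(y_true, y_hat) -> tuple[float, float, float, float]:
    """(rmse, mae, sd_abs_err, r2); R^2 needs a non-constant reference."""
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y_true) != len(y_hat) or len(y_true) == 0:
        raise ValueError("y_true and y_hat must have equal non-zero length")
    e = y_hat - y_true
    rmse = float(np.sqrt(np.mean(e**2)))
    mae = float(np.mean(np.abs(e)))
    sd_abs = _sd(np.abs(e))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: reference series has zero variance")
    r2 = 1.0 - float(np.sum(e**2)) / ss_tot
    return rmse, mae, sd_abs, r2


def bland_altman(y_true, y_hat) -> tuple[float, float, float]:
    """(mean_diff, loa_low, loa_high) with diffs = estimate - reference."""
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y_true) != len(y_hat) or len(y_true) < 2:
        raise ValueError("need equal lengths >= 2")
    d = y_hat - y_true
    m = float(np.mean(d))
    half = 1.96 * _sd(d)
    return m, m - half, m + half


def aami_check(y_true, y_hat, n_subjects: int | None = None
               ) -> tuple[float, float, bool, bool]:
    """(mean_error, sd_error, passed, population_sufficient)."""
    e = np.asarray(y_hat, dtype=float) - np.asarray(y_true, dtype=float)
    if len(e) < 2:
        raise ValueError("need n >= 2")
    mean_e = float(np.mean(e))
    sd_e = _sd(e)
    passed = abs(mean_e) <= AAMI_MEAN_LIMIT and sd_e <= AAMI_SD_LIMIT
    sufficient = n_subjects is None or n_subjects >= AAMI_MIN_SUBJECTS
    return mean_e, sd_e, passed, sufficient


def bhs_grade(y_true, y_hat) -> tuple[float, float, float, str]:
    """(p5, p10, p15, grade): cumulative |error| percentages and the grade."""
    e = np.abs(np.asarray(y_hat, dtype=float) - np.asarray(y_true, dtype=float))
    if len(e) == 0:
        raise ValueError("need n >= 1")
    p5, p10, p15 = (100.0 * float(np.mean(e <= k)) for k in (5.0, 10.0, 15.0))
    grade = "D"
    for g, (t5, t10, t15) in BHS_THRESHOLDS.items():
        if p5 >= t5 and p10 >= t10 and p15 >= t15:
            grade = g
            break
    return p5, p10, p15, grade


@dataclass
class AttentionSectionMap:
    """Mapping of attention timesteps back onto window samples/seconds."""

    boundaries_samples: list[tuple[int, int]]
    durations_ms: list[float]
    time_before_target_s: list[float]  # window end to each section's end
    mean_weight: list[float]


def attention_sections(attention: np.ndarray, window_len: int = 625,
                       fs: float = 125.0) -> AttentionSectionMap:
    """Assign attention weights to input-signal sections.

    With four stride-3 ceil-mode pools, each of the first T-1 timesteps
    covers ``3**4 = 81`` samples and the last covers the remainder (58 for a
    625-sample window).
    """
    attention = np.atleast_2d(np.asarray(attention, dtype=float))
    T = attention.shape[1]
    step = 3**4
    expected_T = -(-window_len // step)
    if T != expected_T:
        raise ValueError(
            f"attention length {T} inconsistent with window_len {window_len} "
            f"(expected {expected_T})")
    bounds = [(k * step, min((k + 1) * step, window_len)) for k in range(T)]
    durations = [1000.0 * (b - a) / fs for a, b in bounds]
    before_target = [(window_len - b) / fs for _, b in bounds]
    mean_w = attention.mean(axis=0).tolist()
    return AttentionSectionMap(bounds, durations, before_target, mean_w)


@dataclass
class EvalReport:
    """Full metrics bundle for one estimator on one test set."""

    per_target: dict          # {"sbp": {...}, "dbp": {...}}
    n: int
    n_subjects: int | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, s: str) -> "EvalReport":
        d = json.loads(s)
        return cls(**d)


def _target_block(y_true, y_hat, n_subjects) -> dict:
    rmse, mae, sd_abs, r2 = regression_metrics(y_true, y_hat)
    mean_d, lo, hi = bland_altman(y_true, y_hat)
    mean_e, sd_e, passed, sufficient = aami_check(y_true, y_hat, n_subjects)
    p5, p10, p15, grade = bhs_grade(y_true, y_hat)
    return {
        "rmse": rmse, "mae": mae, "sd_abs_err": sd_abs, "r2": r2,
        "bland_altman": {"mean_diff": mean_d, "loa_low": lo, "loa_high": hi},
        "aami": {"mean_error": mean_e, "sd_error": sd_e, "pass": passed,
                 "population_sufficient": sufficient},
        "bhs": {"pct_within_5": p5, "pct_within_10": p10,
                "pct_within_15": p15, "grade": grade},
    }


def evaluate_predictions(sbp_true, sbp_hat, dbp_true, dbp_hat,
                         n_subjects: int | None = None,
                         meta: dict | None = None) -> EvalReport:
    """Build the full report for paired SBP/DBP estimates."""
    return EvalReport(
        per_target={
            "sbp": _target_block(sbp_true, sbp_hat, n_subjects),
            "dbp": _target_block(dbp_true, dbp_hat, n_subjects),
        },
        n=len(np.asarray(sbp_true)),
        n_subjects=n_subjects,
        meta=meta or {},
    )
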