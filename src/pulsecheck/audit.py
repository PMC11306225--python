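"""Train/test split taxonomy, leakage detection, calibration evaluation,
and error metrics with AAMI/BHS grading.

Three split modes reflect how contamination enters physiological-signal
benchmarks (windows from the same patients, records, or raw samples on
both sides of the split):

* ``no_overlap`` — partition at the patient level (the honest split),
* ``domain_overlap`` — partition at the record level; records from the
  same patient may straddle the split, leaking identity,
* ``data_overlap`` — overlapping windows are generated first and then
  split at the window level, so train and test windows can share raw
  samples.

Calibration evaluators implement the per-record constant ("naive": mean
ground truth of the first three windows), additive offset (truth minus
prediction on the first window), or no calibration, and report error bias /
SD plus a decay curve of error SD versus time since calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .waveforms import Cohort, SegmentationSpec, Window, derive_labels, segment

__all__ = [
    "SplitSpec",
    "LeakageReport",
    "CalibrationSpec",
    "ErrorStats",
    "StandardsGrade",
    "overlapping_windows",
    "make_split",
    "detect_leakage",
    "calibrate_and_evaluate",
    "error_stats",
    "grade",
    "ridge_predictor",
    "nearest_window_predictor",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    mode: str  # no_overlap | domain_overlap | data_overlap
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"no_overlap", "domain_overlap", "data_overlap"}:
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class LeakageReport:
    """Contamination counters between a train and a test window set.

    ``overlapping_sample_pairs`` counts train/test window pairs from the
    same record whose sample intervals intersect.  A clean patient-level
    split has all three counters at zero.
    """

    shared_patients: int
    shared_records: int
    overlapping_sample_pairs: int

    @property
    def is_clean(self) -> bool:
        return (
            self.shared_patients == 0
            and self.shared_records == 0
            and self.overlapping_sample_pairs == 0
        )


@dataclass(frozen=True)
class CalibrationSpec:
    """Calibration strategy.

    ``unit`` selects the calibration scope: ``"record"`` calibrates at the
    head of every record (short-record evaluation); ``"patient"``
    calibrates once at the head of each patient's first record and applies
    the constant to all their later windows, which is the scope at which
    calibration decay over days is observable.
    """

    method: str = "naive"  # naive | offset | none
    unit: str = "record"   # record | patient
    n_naive_windows: int = 3

    def __post_init__(self) -> None:
        if self.method not in {"naive", "offset", "none"}:
            raise ValueError(f"unknown calibration method {self.method!r}")
        if self.unit not in {"record", "patient"}:
            raise ValueError("unit must be 'record' or 'patient'")


@dataclass(frozen=True)
class ErrorStats:
    """Prediction-error summary over evaluation windows, mmHg for BP."""

    bias: float
    sd: float
    mae: float
    n: int


@dataclass(frozen=True)
class StandardsGrade:
    """Device-standard grading of an error distribution.

    AAMI: |bias| <= 5 mmHg and error SD <= 8 mmHg (both inclusive).
    BHS: grade from cumulative fractions of |error| within 5/10/15 mmHg —
    A: 60/85/95%, B: 50/75/90%, C: 40/65/85%, else D.
    """

    aami_pass: bool
    bhs_grade: str
    cum5: float
    cum10: float
    cum15: float


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def overlapping_windows(
    cohort: Cohort,
    targets: Sequence[str] = ("SBP",),
    window_s: float = 10.0,
    overlap_s: float = 5.0,
    channel: str = "PPG",
) -> List[Window]:
    """Segment every record into overlapping labeled windows.

    The 10 s / 5 s default reproduces the windowing under which window-level
    random splits leak raw samples between train and test.
    """
    out: List[Window] = []
    spec = SegmentationSpec(window_s=window_s, overlap_s=overlap_s, channel=channel)
    for rec in cohort.records:
        wins = segment(rec, spec)
        out.extend(derive_labels(rec, wins, targets))
    return out


def make_split(
    windows: Sequence[Window],
    spec: SplitSpec,
    cohort: Optional[Cohort] = None,
    targets: Sequence[str] = ("SBP",),
) -> Tuple[List[Window], List[Window]]:
    """Split windows into train and test sets according to the mode.

    ``no_overlap`` partitions patient ids; ``domain_overlap`` partitions
    record ids (patients may straddle); ``data_overlap`` splits windows at
    random — when a ``cohort`` is supplied, 10 s / 5 s overlapping windows
    are regenerated from it first, mirroring pipelines that window before
    splitting.  Seeded and reproducible; train and test never share window
    objects in any mode.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "data_overlap":
        if cohort is not None:
            windows = overlapping_windows(cohort, targets=targets)
        idx = rng.permutation(len(windows))
        n_test = max(1, int(round(spec.test_fraction * len(windows))))
        test_idx = set(idx[:n_test].tolist())
        train = [w for i, w in enumerate(windows) if i not in test_idx]
        test = [w for i, w in enumerate(windows) if i in test_idx]
        return train, test

    if spec.mode == "no_overlap":
        keys = sorted({w.patient_id for w in windows})
        if len(keys) < 2:
            raise ValueError("no_overlap split needs at least 2 patients")
        key_of = lambda w: w.patient_id
    else:  # domain_overlap
        keys = sorted({(w.patient_id, w.record_id) for w in windows})
        if len(keys) < 2:
            raise ValueError("domain_overlap split needs at least 2 records")
        key_of = lambda w: (w.patient_id, w.record_id)
    perm = rng.permutation(len(keys))
    n_test = max(1, int(round(spec.test_fraction * len(keys))))
    test_keys = {keys[i] for i in perm[:n_test]}
    train = [w for w in windows if key_of(w) not in test_keys]
    test = [w for w in windows if key_of(w) in test_keys]
    return train, test


def detect_leakage(train: Sequence[Window], test: Sequence[Window]) -> LeakageReport:
    """Count shared patients, shared records, and raw-sample-overlapping
    train/test window pairs (interval intersection on the same record)."""
    train_p = {w.patient_id for w in train}
    test_p = {w.patient_id for w in test}
    train_r = {(w.patient_id, w.record_id) for w in train}
    test_r = {(w.patient_id, w.record_id) for w in test}
    shared_patients = len(train_p & test_p)
    shared_records = len(train_r & test_r)

    by_record: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for w in train:
        by_record.setdefault((w.patient_id, w.record_id), []).append(
            (w.start_index, w.start_index + len(w))
        )
    n_pairs = 0
    for w in test:
        ivals = by_record.get((w.patient_id, w.record_id))
        if not ivals:
            continue
        lo, hi = w.start_index, w.start_index + len(w)
        for a, b in ivals:
            if a < hi and lo < b:  # half-open interval intersection
                n_pairs += 1
    return LeakageReport(shared_patients, shared_records, n_pairs)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_and_evaluate(
    windows: Sequence[Window],
    predictor: Optional[Callable[[Window], float]],
    spec: CalibrationSpec,
    target: str = "SBP",
    day_bin_s: float = 86400.0,
) -> Tuple[ErrorStats, pd.DataFrame]:
    """Apply a calibration strategy and evaluate post-calibration error.

    ``windows`` must carry the target label and provenance; they are
    grouped per calibration unit and ordered by time.  Calibration windows
    are excluded from evaluation.  ``naive`` predicts the mean ground truth
    of the first ``n_naive_windows`` windows (the predictor is ignored);
    ``offset`` adds ``truth - prediction`` of the first window to every
    later prediction; ``none`` passes predictions through.

    Returns the pooled :class:`ErrorStats` and a decay curve: error SD per
    elapsed-time bin (default 1-day bins) since the calibration window(s).
    Units with too few windows (naive needs ``n_naive_windows + 1``) are
    skipped with a log message.
    """
    labeled = [w for w in windows if target in w.labels and np.isfinite(w.labels[target])]
    groups: Dict[object, List[Window]] = {}
    for w in labeled:
        key = w.patient_id if spec.unit == "patient" else (w.patient_id, w.record_id)
        groups.setdefault(key, []).append(w)

    errors: List[float] = []
    elapsed: List[float] = []
    for key, ws in groups.items():
        ws = sorted(ws, key=lambda w: (w.start_s, w.start_index))
        truths = np.array([w.labels[target] for w in ws])
        if spec.method == "naive":
            n_cal = spec.n_naive_windows
            if len(ws) < n_cal + 1:
                logger.info("skipping %s: %d windows < %d", key, len(ws), n_cal + 1)
                continue
            const = float(np.mean(truths[:n_cal]))
            preds = np.full(len(ws) - n_cal, const)
            eval_ws = ws[n_cal:]
            t_cal = ws[n_cal - 1].start_s
        elif spec.method == "offset":
            if predictor is None:
                raise ValueError("offset calibration needs a predictor")
            if len(ws) < 2:
                logger.info("skipping %s: needs >= 2 windows", key)
                continue
            offset = truths[0] - float(predictor(ws[0]))
            eval_ws = ws[1:]
            preds = np.array([float(predictor(w)) + offset for w in eval_ws])
            t_cal = ws[0].start_s
        else:  # none
            if predictor is None:
                raise ValueError("uncalibrated evaluation needs a predictor")
            eval_ws = ws
            preds = np.array([float(predictor(w)) for w in eval_ws])
            t_cal = ws[0].start_s
        for w, p in zip(eval_ws, preds):
            errors.append(p - w.labels[target])
            elapsed.append(w.start_s - t_cal)

    if not errors:
        raise ValueError("no evaluation windows after calibration")
    err = np.asarray(errors)
    stats = error_stats(err + 0.0, np.zeros_like(err))  # errors already formed
    bins = np.floor(np.asarray(elapsed) / day_bin_s).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = err[bins == b]
        rows.append(
            dict(day_bin=int(b), error_sd=float(np.std(sel)), bias=float(np.mean(sel)), n=len(sel))
        )
    return stats, pd.DataFrame(rows)


def error_stats(predictions: Sequence[float], truths: Sequence[float]) -> ErrorStats:
    """Bias = mean(pred - truth); SD is the population SD of the error."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape or len(p) == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    e = p - t
    return ErrorStats(
        bias=float(np.mean(e)), sd=float(np.std(e)), mae=float(np.mean(np.abs(e))), n=len(e)
    )


def grade(stats: ErrorStats, errors: Sequence[float]) -> StandardsGrade:
    """AAMI pass/fail and BHS letter grade for an error sample."""
    e = np.abs(np.asarray(errors, dtype=float))
    cum5, cum10, cum15 = float(np.mean(e <= 5)), float(np.mean(e <= 10)), float(np.mean(e <= 15))
    aami = abs(stats.bias) <= 5.0 and stats.sd <= 8.0
    if cum5 >= 0.60 and cum10 >= 0.85 and cum15 >= 0.95:
        letter = "A"
    elif cum5 >= 0.50 and cum10 >= 0.75 and cum15 >= 0.90:
        letter = "B"
    elif cum5 >= 0.40 and cum10 >= 0.65 and cum15 >= 0.85:
        letter = "C"
    else:
        letter = "D"
    return StandardsGrade(aami_pass=aami, bhs_grade=letter, cum5=cum5, cum10=cum10, cum15=cum15)


# ---------------------------------------------------------------------------
# Plumbing predictors (exercise the audit machinery; no accuracy claims)
# ---------------------------------------------------------------------------

def ridge_predictor(
    feature_table: pd.DataFrame,
    feature_cols: Sequence[str],
    target: str = "SBP",
    alpha: float = 1.0,
) -> Callable[[Window], float]:
    """Ridge regression on handcrafted features; predicts by row lookup.

    The returned callable maps a Window to a prediction via its
    (patient_id, record_id, start_index) row in ``feature_table``; windows
    without a (complete) feature row get the training-mean prediction.
    """
    df = feature_table.dropna(subset=list(feature_cols) + [target])
    model = Ridge(alpha=alpha)
    model.fit(df[list(feature_cols)].to_numpy(), df[target].to_numpy())
    mean_pred = float(df[target].mean())
    lookup = {
        (r.patient_id, r.record_id, int(r.start_index)): np.array(
            [getattr(r, c) for c in feature_cols], dtype=float
        )
        for r in df.itertuples()
    }

    def predict(w: Window) -> float:
        row = lookup.get((w.patient_id, w.record_id, int(w.start_index)))
        if row is None or not np.all(np.isfinite(row)):
            return mean_pred
        return float(model.predict(row[None, :])[0])

    return predict


def nearest_window_predictor(
    train_windows: Sequence[Window], target: str = "SBP"
) -> Callable[[Window], float]:
    """1-nearest-window predictor on per-window min-max normalized samples.

    A minimal memorizer: it predicts the label of the most similar training
    window.  Useful for demonstrating how leakage inflates accuracy the way
    over-parameterized networks do; never a BP accuracy claim.
    """
    rows = []
    labels = []
    for w in train_windows:
        if target not in w.labels or not np.isfinite(w.labels[target]):
            continue
        v = np.asarray(w.values, dtype=float)
        span = np.ptp(v) or 1.0
        rows.append((v - v.min()) / span)
        labels.append(w.labels[target])
    if not rows:
        raise ValueError("no labeled training windows")
    X = np.stack(rows)
    y = np.asarray(labels)

    def predict(w: Window) -> float:
        v = np.asarray(w.values, dtype=float)
        span = np.ptp(v) or 1.0
        v = (v - v.min()) / span
        if len(v) != X.shape[1]:
            raise ValueError("window length mismatch with training windows")
        d = np.linalg.norm(X - v[None, :], axis=1)
        return float(y[int(np.argmin(d))])

    return predict
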