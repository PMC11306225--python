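"""Multi-valued-mapping checker for ill-conditioned regression tasks.

A prediction task ``y = f(x)`` is ill-conditioned when near-identical
inputs carry very different labels.  The checker scans all window pairs of
a dataset for *matches*: pairs whose cross-correlation-aligned Euclidean
distance in input space is at most ``input_threshold`` while their labels
differ by at least ``output_threshold``.  The reported statistic is the
multi-valued mapping factor: the percentage of windows with at least one
qualifying partner.  A high factor means no single-valued map from input
to label can exist at the measurement noise scale.

Windows are min-max normalized per *record* (not per window) before
distances, keeping relative amplitude information within a record while
making the distance threshold meaningful for an arbitrary-unit sensor.
With the default threshold 1.0 over a 250-sample window, the implied
mean-squared per-sample budget is ``1.0^2 / 250 = 4e-3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .waveforms import Window

__all__ = [
    "DEFAULT_OUTPUT_THRESHOLDS",
    "MvMapConfig",
    "MatchPair",
    "MvMapReport",
    "align",
    "pair_distance",
    "normalize_per_record",
    "find_matches",
]

#: Output thresholds in task units: SBP mmHg, HR bpm, RWAT s.
DEFAULT_OUTPUT_THRESHOLDS: Dict[str, float] = {"SBP": 8.0, "HR": 8.0, "RWAT": 0.02}


@dataclass(frozen=True)
class MvMapConfig:
    """Thresholds and scope for the pair search.

    ``input_threshold`` is an L2 distance over the full window on the
    per-record [0, 1] scale.  ``scope`` restricts partners to the same
    patient (``intra_patient``) or to different patients
    (``inter_patient``); the two scopes partition all pairs.  Alignment
    uses circular shifts up to ``max_lag_s`` chosen by normalized
    cross-correlation.
    """

    input_threshold: float = 1.0
    output_threshold: float = 8.0
    scope: str = "intra_patient"
    max_lag_s: float = 0.5

    def __post_init__(self) -> None:
        if self.input_threshold <= 0 or self.output_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.scope not in {"intra_patient", "inter_patient"}:
            raise ValueError("scope must be intra_patient or inter_patient")


@dataclass(frozen=True)
class MatchPair:
    i: int
    j: int
    distance: float
    label_gap: float
    lag: int


@dataclass
class MvMapReport:
    """Result of one multi-valued-mapping search."""

    n_windows: int
    n_matched: int
    pairs: List[MatchPair] = field(default_factory=list)
    n_unlabeled: int = 0
    target: str = ""
    scope: str = ""

    @property
    def match_fraction(self) -> float:
        """Percent of labeled windows with at least one qualifying partner."""
        return 100.0 * self.n_matched / self.n_windows if self.n_windows else float("nan")


# ---------------------------------------------------------------------------
# Alignment and distance
# ---------------------------------------------------------------------------

def _lag_order(n: int, max_lag: int) -> np.ndarray:
    """Signed lags ordered 0, +1, -1, +2, -2, ...; first strict max wins,
    so correlation ties resolve toward the smallest |lag|."""
    lags = [0]
    for k in range(1, max_lag + 1):
        lags.extend((k, -k))
    return np.asarray(lags, dtype=int)


def _best_lag(a: np.ndarray, b: np.ndarray, max_lag: int) -> int:
    """Lag maximizing the zero-mean circular cross-correlation of a with
    roll(b, lag), restricted to |lag| <= max_lag."""
    a0 = a - a.mean()
    b0 = b - b.mean()
    if np.dot(a0, a0) == 0 or np.dot(b0, b0) == 0:
        return 0
    n = len(a)
    corr_full = np.fft.irfft(np.fft.rfft(a0) * np.conj(np.fft.rfft(b0)), n)
    lags = _lag_order(n, max_lag)
    corr = corr_full[np.mod(lags, n)]
    return int(lags[int(np.argmax(corr))])


def align(
    x_i: Sequence[float], x_j: Sequence[float], fs: float = 125.0, max_lag_s: float = 0.5
) -> Tuple[np.ndarray, int]:
    """Circularly shift ``x_j`` onto ``x_i`` by the best cross-correlation lag.

    Returns ``(shifted x_j, lag)`` where ``shifted = roll(x_j, lag)``.  If
    ``x_j`` equals ``x_i`` rolled forward by +m samples, the recovered lag
    is -m.  Zero-variance inputs get lag 0 (correlation defined as 0).
    """
    a = np.asarray(x_i, dtype=float)
    b = np.asarray(x_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("windows must have equal length")
    lag = _best_lag(a, b, int(round(max_lag_s * fs)))
    return np.roll(b, lag), lag


def pair_distance(
    x_i: Sequence[float],
    x_j: Sequence[float],
    cfg: MvMapConfig = MvMapConfig(),
    fs: float = 125.0,
) -> float:
    """Euclidean distance between the aligned windows (symmetric)."""
    a = np.asarray(x_i, dtype=float)
    b = np.asarray(x_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("windows must have equal length")
    shifted, _ = align(a, b, fs=fs, max_lag_s=cfg.max_lag_s)
    return float(np.linalg.norm(a - shifted))


def normalize_per_record(windows: Sequence[Window]) -> np.ndarray:
    """Stack window values min-max normalized per (patient, record) to [0, 1]."""
    X = np.stack([np.asarray(w.values, dtype=float) for w in windows])
    keys = [(w.patient_id, w.record_id) for w in windows]
    out = np.empty_like(X)
    for key in set(keys):
        idx = [i for i, k in enumerate(keys) if k == key]
        block = X[idx]
        lo, hi = block.min(), block.max()
        span = hi - lo if hi > lo else 1.0
        out[idx] = (block - lo) / span
    return out


# ---------------------------------------------------------------------------
# Pair search
# ---------------------------------------------------------------------------

def find_matches(
    windows: Sequence[Window],
    target: str,
    cfg: Optional[MvMapConfig] = None,
    prescreen: bool = True,
) -> MvMapReport:
    """Scan all in-scope window pairs for multi-valued mappings.

    A window is *matched* when at least one in-scope partner is within
    ``input_threshold`` after alignment AND differs in label by at least
    ``output_threshold`` (both thresholds boundary-inclusive).  Unlabeled
    windows are excluded from the scan and counted in ``n_unlabeled``.

    ``prescreen=True`` skips pairs whose distance lower bound
    ``| ||x_i|| - ||x_j|| |`` (circular shifts preserve norms) exceeds the
    input threshold; the screen is exact and never changes the report.
    The scan is O(n^2) pairs with FFT-based alignment.
    """
    if cfg is None:
        cfg = MvMapConfig(output_threshold=DEFAULT_OUTPUT_THRESHOLDS.get(target, 8.0))
    labeled = [
        w for w in windows if target in w.labels and np.isfinite(w.labels[target])
    ]
    n_unlabeled = len(windows) - len(labeled)
    n = len(labeled)
    report = MvMapReport(
        n_windows=n, n_matched=0, n_unlabeled=n_unlabeled, target=target, scope=cfg.scope
    )
    if n < 2:
        return report

    fs = labeled[0].fs
    X = normalize_per_record(labeled)
    L = X.shape[1]
    y = np.array([w.labels[target] for w in labeled], dtype=float)
    pids = np.array([w.patient_id for w in labeled])
    norms = np.linalg.norm(X, axis=1)
    sq = norms**2

    max_lag = int(round(cfg.max_lag_s * fs))
    lags = _lag_order(L, max_lag)
    lag_idx = np.mod(lags, L)

    X0 = X - X.mean(axis=1, keepdims=True)
    zero_var = np.einsum("ij,ij->i", X0, X0) == 0
    F0 = np.fft.rfft(X0, axis=1)
    F = np.fft.rfft(X, axis=1)

    matched = np.zeros(n, dtype=bool)
    pairs: List[MatchPair] = []

    for i in range(n - 1):
        j = np.arange(i + 1, n)
        same = pids[j] == pids[i]
        in_scope = same if cfg.scope == "intra_patient" else ~same
        cand = j[in_scope & (np.abs(y[j] - y[i]) >= cfg.output_threshold)]
        if prescreen and len(cand):
            cand = cand[np.abs(norms[cand] - norms[i]) <= cfg.input_threshold]
        if len(cand) == 0:
            continue
        # lag choice from zero-mean correlation, all candidates at once
        corr = np.fft.irfft(F0[i][None, :] * np.conj(F0[cand]), L, axis=1)[:, lag_idx]
        best = np.argmax(corr, axis=1)  # first occurrence: smallest |lag| wins
        best_lags = lags[best]
        best_lags[zero_var[cand] | zero_var[i]] = 0
        # aligned distance from the raw circular correlation at the chosen lag
        raw = np.fft.irfft(F[i][None, :] * np.conj(F[cand]), L, axis=1)
        dots = raw[np.arange(len(cand)), np.mod(best_lags, L)]
        d2 = np.maximum(sq[i] + sq[cand] - 2.0 * dots, 0.0)
        dist = np.sqrt(d2)
        hits = dist <= cfg.input_threshold
        for jj, d, lg in zip(cand[hits], dist[hits], best_lags[hits]):
            matched[i] = True
            matched[jj] = True
            pairs.append(
                MatchPair(
                    i=i, j=int(jj), distance=float(d),
                    label_gap=float(abs(y[jj] - y[i])), lag=int(lg),
                )
            )
    report.n_matched = int(matched.sum())
    report.pairs = pairs
    return report
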