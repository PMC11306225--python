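"""Beat detection and handcrafted pulse-wave features, plus an MLP
autoencoder featurizer.

The handcrafted set is the classic pulse-wave-analysis battery: heart rate
(inverse median inter-beat interval), heart-rate variability (SDNN), a
composite signal-quality score, the normalized systolic ramp (dp/dt),
radial pulse arrival time rPAT (ECG R-peak to PPG systolic peak) and its
inverse, plus per-subject delta features and fixed-period fluctuation
(std) features.  The autoencoder is a five-layer ReLU MLP with a 20-unit
bottleneck trained to reconstruct normalized fixed-length PPG windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from scipy.signal import find_peaks
from sklearn.neural_network import MLPRegressor

from .preprocess import PreprocessConfig, autocorr_quality, bandpass
from .waveforms import SignalRecord, SegmentationSpec, Window, segment

__all__ = [
    "BeatSet",
    "AutoencoderConfig",
    "Autoencoder",
    "detect_beats",
    "detect_r_peaks",
    "heart_rate",
    "sdnn",
    "quality_score",
    "systolic_ramp",
    "rpat",
    "delta_and_std_features",
    "fit_autoencoder",
    "encode",
    "extract_features",
]

logger = logging.getLogger(__name__)

# Physiologic inter-beat interval range used for NN-interval cleaning, s.
_IBI_RANGE = (0.27, 2.0)
_MIN_BEAT_SEPARATION_S = 0.33


@dataclass
class BeatSet:
    """Detected beat positions on one channel (sample indices, increasing)."""

    channel: str
    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("beat indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    def intervals(self) -> np.ndarray:
        """All inter-beat intervals, s."""
        return np.diff(self.indices) / self.fs

    def nn_intervals(self) -> np.ndarray:
        """Normal-to-normal intervals: those within the physiologic range."""
        ibi = self.intervals()
        return ibi[(ibi >= _IBI_RANGE[0]) & (ibi <= _IBI_RANGE[1])]

    def in_window(self, lo: int, hi: int) -> "BeatSet":
        mask = (self.indices >= lo) & (self.indices < hi)
        return BeatSet(self.channel, self.indices[mask], self.fs)


def detect_beats(ppg: Sequence[float], fs: float) -> BeatSet:
    """PPG systolic peaks: local maxima above a rolling 75th percentile.

    The adaptive threshold is the 75th percentile over a ~2-s neighborhood,
    so slow amplitude changes do not defeat detection; candidate peaks
    closer than 0.33 s are merged (highest wins), and secondary waves
    (reflected/dicrotic bumps) are rejected by requiring each peak to reach
    half the local peak amplitude (maximum over +/-0.75 s), which is
    scale-invariant.  Deterministic.  A window with fewer than 2 detectable
    beats yields an (almost) empty beat set and downstream interval
    features are reported missing, never zero.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    x = np.asarray(ppg, dtype=float)
    x = np.where(np.isfinite(x), x, 0.0)
    if len(x) < 3 or np.ptp(x) == 0:
        return BeatSet("PPG", np.empty(0, dtype=int), fs)
    size = max(3, int(round(2.0 * fs)) | 1)
    thresh = percentile_filter(x, 75, size=size, mode="nearest")
    peaks, _ = find_peaks(x, distance=max(1, int(round(_MIN_BEAT_SEPARATION_S * fs))))
    peaks = peaks[x[peaks] >= thresh[peaks]]
    if len(peaks):
        half = max(1, int(round(0.75 * fs)))
        local_max = maximum_filter1d(x, 2 * half + 1, mode="nearest")
        local_min = minimum_filter1d(x, 2 * half + 1, mode="nearest")
        rel = (x[peaks] - local_min[peaks]) / np.maximum(
            local_max[peaks] - local_min[peaks], 1e-12
        )
        peaks = peaks[rel >= 0.5]
    return BeatSet("PPG", peaks, fs)


def detect_r_peaks(ecg: Sequence[float], fs: float) -> BeatSet:
    """ECG R-peaks via an amplitude threshold on the squared derivative.

    A stripped-down Pan-Tompkins: squared first difference, threshold at a
    fraction of its high quantile, 0.33-s refractory period, then the R
    location is refined to the ECG maximum within +/-30 ms.
    """
    x = np.asarray(ecg, dtype=float)
    x = np.where(np.isfinite(x), x, 0.0)
    if len(x) < 3 or np.ptp(x) == 0:
        return BeatSet("ECG", np.empty(0, dtype=int), fs)
    energy = np.diff(x) ** 2
    height = 0.2 * np.quantile(energy, 0.999)
    if height <= 0:
        return BeatSet("ECG", np.empty(0, dtype=int), fs)
    cand, _ = find_peaks(
        energy, height=height, distance=max(1, int(round(_MIN_BEAT_SEPARATION_S * fs)))
    )
    half = max(1, int(round(0.03 * fs)))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    return BeatSet("ECG", refined, fs)


def heart_rate(beats: BeatSet) -> Optional[float]:
    """60 / median inter-beat interval, bpm; None with fewer than 2 beats."""
    if len(beats) < 2:
        return None
    ibi = beats.nn_intervals()
    if len(ibi) == 0:
        ibi = beats.intervals()
    return float(60.0 / np.median(ibi))


def sdnn(beats: BeatSet, subdivision_s: float = 60.0) -> Optional[float]:
    """SDNN: population SD of NN intervals, s; None with fewer than 3 beats.

    When the beat span reaches ``subdivision_s``, the span is subdivided
    into consecutive periods of that length and the mean of per-period SDs
    is returned (short windows are a single period).
    """
    if len(beats) < 3:
        return None
    times = beats.indices / beats.fs
    ibi = np.diff(beats.indices) / beats.fs
    valid = (ibi >= _IBI_RANGE[0]) & (ibi <= _IBI_RANGE[1])
    if valid.sum() < 2:
        return None
    span = times[-1] - times[0]
    if span < subdivision_s:
        return float(np.std(ibi[valid]))
    sds = []
    t_end = times[1:]  # interval i ends at beat i+1
    for k in range(int(np.ceil(span / subdivision_s))):
        lo = times[0] + k * subdivision_s
        mask = valid & (t_end >= lo) & (t_end < lo + subdivision_s)
        if mask.sum() >= 2:
            sds.append(np.std(ibi[mask]))
    return float(np.mean(sds)) if sds else None


def _dropout_fraction(x: np.ndarray, fs: float, min_run_s: float = 0.08) -> float:
    """Fraction of samples inside constant runs of at least ``min_run_s``."""
    n = len(x)
    if n == 0:
        return 0.0
    min_run = max(2, int(round(min_run_s * fs)))
    same = np.diff(x) == 0
    frac = 0
    run = 0
    for s in same:
        if s:
            run += 1
        else:
            if run + 1 >= min_run:
                frac += run + 1
            run = 0
    if run + 1 >= min_run:
        frac += run + 1
    return frac / n


def quality_score(
    window: Window,
    cfg: PreprocessConfig = PreprocessConfig(),
    beats: Optional[BeatSet] = None,
) -> float:
    """Composite signal quality in [0, 1].

    Mean of up to three clamped components: (a) autocorrelation
    self-similarity, (b) fraction of samples outside dropout/clipping runs,
    (c) mean pairwise correlation of per-beat templates (consistency
    between the pulses).  Components whose preconditions fail (e.g. fewer
    than 2 beats for (c)) are excluded from the mean; a fully degenerate
    window scores 0.
    """
    x = np.asarray(window.values, dtype=float)
    if len(x) == 0 or not np.all(np.isfinite(x)) or np.ptp(x) == 0:
        return 0.0
    components = []
    components.append(float(np.clip(autocorr_quality(window, cfg), 0.0, 1.0)))
    components.append(float(np.clip(1.0 - _dropout_fraction(x, window.fs), 0.0, 1.0)))
    if beats is None:
        beats = detect_beats(x, window.fs)
    templ = _beat_templates(x, beats)
    if len(templ) >= 2:
        corr = np.corrcoef(templ)
        upper = corr[np.triu_indices(len(templ), k=1)]
        upper = upper[np.isfinite(upper)]
        if len(upper):
            components.append(float(np.clip(np.mean(upper), 0.0, 1.0)))
    return float(np.mean(components)) if components else 0.0


def _beat_templates(x: np.ndarray, beats: BeatSet, n_resample: int = 50) -> np.ndarray:
    """Per-beat segments (peak to peak), resampled to a common length."""
    idx = beats.indices
    segs = []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = x[a:b]
        if len(seg) < 4 or np.ptp(seg) == 0:
            continue
        pos = np.linspace(0, len(seg) - 1, n_resample)
        segs.append(np.interp(pos, np.arange(len(seg)), seg))
    return np.asarray(segs)


def systolic_ramp(window: Window, beats: Optional[BeatSet] = None) -> Optional[float]:
    """Mean normalized systolic ramp dp/dt over complete beats.

    For each beat the foot is the waveform minimum between consecutive
    systolic peaks; the per-beat ramp is (peak value - foot value) /
    (peak time - foot time), normalized by multiplying with that beat's
    duration (time between the flanking peaks), giving amplitude units per
    beat fraction.  None when no complete foot-to-peak pair exists.
    """
    x = np.asarray(window.values, dtype=float)
    if beats is None:
        beats = detect_beats(x, window.fs)
    idx = beats.indices
    if len(idx) < 2:
        return None
    ramps = []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = x[a:b]
        if len(seg) < 2:
            continue
        foot = a + int(np.argmin(seg))
        if foot >= b or x[b] <= x[foot]:
            continue
        rise_t = (b - foot) / window.fs
        if rise_t <= 0:
            continue
        ramp = (x[b] - x[foot]) / rise_t
        duration = (b - a) / window.fs
        ramps.append(ramp * duration)
    return float(np.mean(ramps)) if ramps else None


def rpat(
    ecg_beats: BeatSet, ppg_beats: BeatSet, max_delay_s: float = 0.6
) -> Optional[float]:
    """Radial pulse arrival time: median ECG-R to PPG-systolic-peak delay, s.

    For each PPG peak the nearest preceding R-peak within ``max_delay_s``
    is used; None when no PPG peak has a preceding R-peak.
    """
    if len(ecg_beats) == 0 or len(ppg_beats) == 0:
        return None
    if ecg_beats.fs != ppg_beats.fs:
        raise ValueError("beat sets must share a sampling rate")
    fs = ppg_beats.fs
    r = ecg_beats.indices
    delays = []
    for p in ppg_beats.indices:
        k = np.searchsorted(r, p, side="right") - 1
        if k < 0:
            continue
        d = (p - r[k]) / fs
        if 0 < d <= max_delay_s:
            delays.append(d)
    return float(np.median(delays)) if delays else None


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_FEATURE_COLS = ["HR", "HRV_SDNN", "Quality", "dpdt", "rPAT", "invPAT"]


def extract_features(
    record: SignalRecord,
    windows: Optional[Sequence[Window]] = None,
    window_s: float = 2.0,
    apply_bandpass: bool = True,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> pd.DataFrame:
    """Handcrafted feature table for one record, one row per window.

    Beats are detected once on the (optionally band-passed) full PPG
    channel; ECG R-peaks likewise when an ECG channel is present, enabling
    rPAT/invPAT.  HR is computed from the PPG pulse train (the ECG is used
    only for arrival-time features).  Missing features are NaN, with the
    reason flagged in the ``qc_flags`` column.
    """
    if "PPG" not in record.channels:
        raise KeyError("record has no PPG channel")
    ppg = record.channels["PPG"]
    finite_ppg = np.where(np.isfinite(ppg), ppg, 0.0)
    sig = bandpass(finite_ppg, record.fs, cfg) if apply_bandpass else finite_ppg
    ppg_beats = detect_beats(sig, record.fs)
    ecg_beats = None
    if "ECG" in record.channels:
        ecg_beats = detect_r_peaks(record.channels["ECG"], record.fs)

    if windows is None:
        windows = segment(record, SegmentationSpec(window_s=window_s, channel="PPG"))

    rows = []
    for w in windows:
        lo, hi = w.start_index, w.start_index + len(w)
        wb = ppg_beats.in_window(lo, hi)
        sig_win = Window(
            patient_id=w.patient_id,
            record_id=w.record_id,
            start_index=lo,
            values=sig[lo:hi],
            fs=record.fs,
            channel="PPG",
            t0_s=record.t0_s,
        )
        flags = []
        hr = heart_rate(wb)
        if hr is None:
            flags.append("HR_missing")
        hrv = sdnn(wb)
        if hrv is None:
            flags.append("HRV_missing")
        # quality/ramp work on window-local indices
        wb_local = BeatSet("PPG", wb.indices - lo, record.fs)
        qual = quality_score(sig_win, cfg, beats=wb_local)
        ramp = systolic_ramp(sig_win, beats=wb_local)
        if ramp is None:
            flags.append("dpdt_missing")
        pat = None
        if ecg_beats is not None:
            pat = rpat(ecg_beats.in_window(max(0, lo - int(0.6 * record.fs)), hi), wb)
        if pat is None and ecg_beats is not None:
            flags.append("rPAT_missing")
        rows.append(
            dict(
                patient_id=w.patient_id,
                record_id=w.record_id,
                start_index=lo,
                t_s=w.start_s,
                HR=np.nan if hr is None else hr,
                HRV_SDNN=np.nan if hrv is None else hrv,
                Quality=qual,
                dpdt=np.nan if ramp is None else ramp,
                rPAT=np.nan if pat is None else pat,
                invPAT=np.nan if (pat is None or pat <= 0) else 1.0 / pat,
                hr_source="PPG",
                qc_flags=";".join(flags),
                **{k: v for k, v in w.labels.items()},
            )
        )
    return pd.DataFrame(rows)


def delta_and_std_features(
    table: pd.DataFrame,
    baseline: pd.DataFrame,
    feature_cols: Optional[Sequence[str]] = None,
    period_s: float = 60.0,
    window_s: float = 2.0,
) -> pd.DataFrame:
    """Per-subject delta features and fixed-period fluctuation features.

    ``delta_<f>`` is the row value minus the subject's mean over the
    ``baseline`` rows (e.g. the designated at-rest record); subjects absent
    from the baseline get NaN deltas.  ``std_<f>`` is the population SD of
    ``f`` over the consecutive windows spanning ``period_s`` up to and
    including each row, computed within each record in time order.
    """
    if feature_cols is None:
        feature_cols = [c for c in _FEATURE_COLS if c in table.columns]
    out = table.copy()
    base_means = baseline.groupby("patient_id")[list(feature_cols)].mean()
    for c in feature_cols:
        ref = out["patient_id"].map(base_means[c])
        out[f"delta_{c}"] = out[c] - ref
    n_roll = max(2, int(round(period_s / window_s)))
    out = out.sort_values(["patient_id", "record_id", "start_index"]).reset_index(drop=True)
    for c in feature_cols:
        out[f"std_{c}"] = (
            out.groupby(["patient_id", "record_id"])[c]
            .transform(lambda s: s.rolling(n_roll, min_periods=2).std(ddof=0))
        )
    return out


# ---------------------------------------------------------------------------
# Autoencoder featurizer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AutoencoderConfig:
    """Five-layer ReLU MLP autoencoder: input-128-20-128-input.

    Trained with Adam (step size ``learning_rate``) on mean squared
    reconstruction error of min-max normalized windows; training stops when
    the epoch loss drops below ``loss_target`` or at ``max_epochs``.
    """

    bottleneck: int = 20
    hidden: int = 128
    learning_rate: float = 1e-3
    loss_target: float = 0.1
    max_epochs: int = 200
    batch_size: int = 128
    seed: int = 0


@dataclass
class Autoencoder:
    model: MLPRegressor
    config: AutoencoderConfig
    final_loss: float
    n_epochs: int
    converged: bool


def _window_matrix(windows) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        X = np.asarray(windows, dtype=float)
    else:
        X = np.stack([np.asarray(w.values, dtype=float) for w in windows])
    lo = X.min(axis=1, keepdims=True)
    span = np.ptp(X, axis=1, keepdims=True)
    span[span == 0] = 1.0
    return (X - lo) / span


def fit_autoencoder(windows, cfg: AutoencoderConfig = AutoencoderConfig()) -> Autoencoder:
    """Fit the autoencoder on min-max normalized windows.

    ``windows`` is a sequence of equal-length Window objects or an (n, L)
    array.  Fewer than ~500 windows gives an under-determined fit and is
    logged.  Non-convergence at the epoch cap returns the encoder anyway
    with ``converged=False`` and the final loss recorded.
    """
    X = _window_matrix(windows)
    n = len(X)
    if n < 500:
        logger.warning("autoencoder fit on only %d windows (<500)", n)
    if cfg.bottleneck >= X.shape[1]:
        raise ValueError("bottleneck must be smaller than the window length")
    model = MLPRegressor(
        hidden_layer_sizes=(cfg.hidden, cfg.bottleneck, cfg.hidden),
        activation="relu",
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        batch_size=min(cfg.batch_size, n),
        random_state=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    loss = np.inf
    epoch = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial_fit emits convergence chatter
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            for s in range(0, n, cfg.batch_size):
                batch = X[order[s : s + cfg.batch_size]]
                model.partial_fit(batch, batch)
            loss = float(np.mean((model.predict(X) - X) ** 2))
            if loss < cfg.loss_target:
                break
    converged = loss < cfg.loss_target
    if not converged:
        logger.warning(
            "autoencoder did not reach loss %.3g in %d epochs (final %.3g)",
            cfg.loss_target, cfg.max_epochs, loss,
        )
    return Autoencoder(model=model, config=cfg, final_loss=loss, n_epochs=epoch, converged=converged)


def encode(ae: Autoencoder, windows) -> np.ndarray:
    """Bottleneck embeddings, (n, bottleneck); deterministic given a fit."""
    X = _window_matrix(windows)
    h = X
    for layer in range(2):  # input->hidden, hidden->bottleneck
        h = np.maximum(h @ ae.model.coefs_[layer] + ae.model.intercepts_[layer], 0.0)
    return h
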