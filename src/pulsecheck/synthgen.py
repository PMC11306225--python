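"""Synthetic multi-patient PPG/ABP/ECG cohorts with controllable conditioning.

The generator exists so that every audit in this package can be exercised on
data whose ground truth is known exactly.  Each patient has a baseline
systolic pressure; within a record, SBP follows a slow AR(1) fluctuation
plus an optional linear drift (mmHg/day) and, in *ill* conditioning mode, a
latent per-window component that moves blood pressure without moving the
PPG at all.  PPG morphology (heart rate, reflected-wave arrival time,
amplitude) is a deterministic invertible function of the PPG-visible part of
SBP, so:

* ``conditioning="well"`` — the waveform determines SBP exactly; windows
  with identical morphology have identical SBP.
* ``conditioning="ill"`` — windows with identical morphology can differ in
  SBP by ~``latent_sd`` mmHg: a planted multi-valued mapping.

Beats are a two-Gaussian template (systolic bump + smaller reflected bump
delayed by RWAT).  The ABP channel is rendered so that its systolic peaks
equal the true per-window SBP; the ECG channel carries impulse-like R-waves
preceding each PPG systolic peak by a per-patient pulse-arrival delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .waveforms import Cohort, SignalRecord

__all__ = [
    "NoiseConfig",
    "ScenarioConfig",
    "GroundTruth",
    "generate_beat",
    "generate_cohort",
    "inject_artifacts",
]

# Reference SBP span used for the invertible SBP -> morphology maps, mmHg.
_SBP_REF = (80.0, 200.0)
# AR(1) coefficient per window step: SBP varies slowly within a record.
_AR_COEF = 0.99
_AR_INNOV_SD = 0.5  # mmHg per 2-s step -> stationary SD ~3.5 mmHg


@dataclass(frozen=True)
class NoiseConfig:
    """Artifact intensities, expressed relative to the pulse amplitude.

    Defaults emulate a moderately corrupted wearable recording: slow
    baseline wander, high-frequency noise, occasional transmission dropouts
    (runs of exact zeros) and step changes in amplitude.
    """

    baseline_wander_amp: float = 0.1   # fraction of peak-to-peak amplitude
    hf_noise_sd: float = 0.05          # fraction of peak-to-peak amplitude
    dropout_rate: float = 0.5          # events per minute
    amplitude_jump_rate: float = 0.5   # events per minute

    def __post_init__(self) -> None:
        for name in ("baseline_wander_amp", "hf_noise_sd", "dropout_rate", "amplitude_jump_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-condition dial for one synthetic cohort."""

    n_patients: int = 10
    records_per_patient: int = 2
    record_s: float = 360.0          # MIMIC-style ~6-minute records
    fs: float = 125.0
    hr_range: Tuple[float, float] = (55.0, 110.0)       # bpm
    sbp_baseline_range: Tuple[float, float] = (100.0, 160.0)  # mmHg
    conditioning: str = "well"       # "well" | "ill"
    latent_sd: float = 0.0           # mmHg, PPG-invisible SBP component (ill mode)
    drift_per_day: float = 0.0       # mmHg/day: SD of the per-patient PPG-invisible
                                     # drift rate, for calibration audits
    patient_idiosyncrasy_sd: float = 0.0  # mmHg, per-patient PPG-invisible offset
    rwat_range: Tuple[float, float] = (0.15, 0.35)      # s
    noise: Optional[NoiseConfig] = None                 # None -> clean records
    seed: int = 0
    label_window_s: float = 2.0      # ground-truth bookkeeping granularity
    record_spacing_days: float = 0.0  # gap between a patient's records
    pat_range: Tuple[float, float] = (0.15, 0.25)       # s, ECG-R -> PPG-peak delay

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")
        if self.conditioning not in {"well", "ill"}:
            raise ValueError("conditioning must be 'well' or 'ill'")
        for lo, hi in (self.hr_range, self.sbp_baseline_range, self.rwat_range, self.pat_range):
            if not lo < hi:
                raise ValueError("ranges must be non-empty (lo < hi)")


@dataclass
class GroundTruth:
    """Per-window generator bookkeeping: one row per emitted window.

    Columns: patient_id, record_id, start_index, t_s (patient clock),
    sbp (true, mmHg), hr (bpm), rwat (s), pat (s), visible (PPG-visible SBP
    part), latent (mmHg), drift (mmHg).
    """

    frame: pd.DataFrame

    def rwat_lookup(self, patient_id: str, record_id: str) -> Dict[int, float]:
        sub = self.frame[
            (self.frame.patient_id == patient_id) & (self.frame.record_id == record_id)
        ]
        return dict(zip(sub.start_index.astype(int), sub.rwat.astype(float)))

    def record_rows(self, patient_id: str, record_id: str) -> pd.DataFrame:
        return self.frame[
            (self.frame.patient_id == patient_id) & (self.frame.record_id == record_id)
        ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Beat template
# ---------------------------------------------------------------------------

def generate_beat(
    hr: float,
    rwat: float,
    amp: float,
    fs: float,
    rise_frac: float = 0.07,
    refl_amp_frac: float = 0.35,
) -> np.ndarray:
    """One PPG beat: systolic Gaussian bump + reflected bump delayed by RWAT.

    The beat spans one period ``60/hr`` seconds; the systolic bump is
    centred at 20% of the period with width ``rise_frac`` of the period; the
    reflected bump follows ``rwat`` seconds later at ``refl_amp_frac`` of
    the systolic height.  The waveform is rescaled so its maximum is ``amp``
    and is everywhere >= 0.  Deterministic.
    """
    if not (30.0 <= hr <= 220.0):
        raise ValueError(f"hr {hr} outside [30, 220] bpm")
    period = 60.0 / hr
    if not (0.0 < rwat < period):
        raise ValueError(f"rwat {rwat} s must lie in (0, beat period {period:.3g} s)")
    n = int(round(period * fs))
    t = np.arange(n) / fs
    t_sys = 0.2 * period
    sigma_sys = rise_frac * period
    sigma_refl = 1.6 * sigma_sys
    beat = np.exp(-0.5 * ((t - t_sys) / sigma_sys) ** 2)
    beat = beat + refl_amp_frac * np.exp(-0.5 * ((t - t_sys - rwat) / sigma_refl) ** 2)
    return amp * beat / beat.max()


def _affine(x: np.ndarray, src: Tuple[float, float], dst: Tuple[float, float]) -> np.ndarray:
    return dst[0] + (dst[1] - dst[0]) * (x - src[0]) / (src[1] - src[0])


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: ScenarioConfig) -> Tuple[Cohort, GroundTruth]:
    """Generate a seeded multi-patient cohort plus exact per-window truth.

    The SBP process per record, at window step ``w`` (``label_window_s``
    apart), is ``baseline + AR(1) fluctuation + rate_p * t_days +
    idiosyncrasy_p``; ill mode adds an i.i.d. ``N(0, latent_sd^2)``
    per-window latent term.  Morphology (hr, rwat, amplitude) is an affine
    function of the *visible* part ``baseline + AR(1)`` only: the latent
    term, the slow drift (per-patient rate drawn with SD ``drift_per_day``)
    and the per-patient idiosyncratic offset are all invisible in the PPG —
    they model the blood-pressure variation that pulse morphology cannot
    carry (unexplained slow change; between-subject differences in the
    morphology-to-pressure relation).  A fixed seed reproduces the cohort
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    win_len = int(round(config.label_window_s * fs))
    rec_len = int(round(config.record_s * fs))
    n_windows = rec_len // win_len
    if n_windows < 1:
        raise ValueError("record_s shorter than one label window")

    records = []
    truth_rows = []
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        baseline = rng.uniform(*config.sbp_baseline_range)
        pat_delay = rng.uniform(*config.pat_range)
        drift_rate = rng.normal(0.0, config.drift_per_day) if config.drift_per_day > 0 else 0.0
        idio = (
            rng.normal(0.0, config.patient_idiosyncrasy_sd)
            if config.patient_idiosyncrasy_sd > 0
            else 0.0
        )
        for r in range(config.records_per_patient):
            rid = f"{pid}_R{r:02d}"
            t0_s = r * config.record_spacing_days * 86400.0

            # slowly varying AR(1) fluctuation, stationary initialization
            stat_sd = _AR_INNOV_SD / np.sqrt(1.0 - _AR_COEF**2)
            fluct = np.empty(n_windows)
            fluct[0] = rng.normal(0.0, stat_sd)
            innov = rng.normal(0.0, _AR_INNOV_SD, size=n_windows - 1)
            for w in range(1, n_windows):
                fluct[w] = _AR_COEF * fluct[w - 1] + innov[w - 1]

            t_s = t0_s + np.arange(n_windows) * config.label_window_s
            drift = drift_rate * t_s / 86400.0
            visible = baseline + fluct
            if config.conditioning == "ill" and config.latent_sd > 0:
                latent = rng.normal(0.0, config.latent_sd, size=n_windows)
            else:
                latent = np.zeros(n_windows)
            sbp = visible + drift + latent + idio

            hr = _affine(visible, _SBP_REF, config.hr_range)
            rwat = _affine(visible, _SBP_REF, (config.rwat_range[1], config.rwat_range[0]))
            ampl = _affine(visible, _SBP_REF, (0.9, 1.2))
            # keep beat parameters physical even for extreme baselines
            hr = np.clip(hr, 31.0, 219.0)
            rwat = np.clip(rwat, 0.02, 0.45)

            ppg, abp, ecg = _render_record(
                sbp, hr, rwat, ampl, pat_delay, fs, win_len, rec_len, rng
            )
            record = SignalRecord(
                patient_id=pid,
                record_id=rid,
                channels={"PPG": ppg, "ABP": abp, "ECG": ecg},
                fs=fs,
                t0_s=t0_s,
            )
            if config.noise is not None:
                record = inject_artifacts(
                    record, config.noise, seed=int(rng.integers(0, 2**31 - 1))
                )
            records.append(record)
            for w in range(n_windows):
                truth_rows.append(
                    dict(
                        patient_id=pid,
                        record_id=rid,
                        start_index=w * win_len,
                        t_s=t_s[w],
                        sbp=sbp[w],
                        hr=hr[w],
                        rwat=rwat[w],
                        pat=pat_delay,
                        visible=visible[w],
                        latent=latent[w],
                        drift=drift[w],
                        idiosyncrasy=idio,
                    )
                )
    return Cohort(records), GroundTruth(pd.DataFrame(truth_rows))


def _render_record(sbp, hr, rwat, ampl, pat_delay, fs, win_len, rec_len, rng):
    """Render PPG/ABP/ECG beat by beat.

    Each beat takes its morphology from the label window containing its
    onset; its ABP peak height is the true SBP of the window containing the
    systolic *peak*, so the mean-of-peaks window label equals the truth.
    """
    n_windows = len(sbp)
    ppg = np.zeros(rec_len)
    abp = np.zeros(rec_len)
    ecg = np.zeros(rec_len)
    spike_half = max(1, int(round(0.006 * fs)))  # ~6 ms half-width R-wave
    spike = np.exp(-0.5 * (np.arange(-3 * spike_half, 3 * spike_half + 1) / spike_half) ** 2)

    cursor = 0
    while True:
        w = min(cursor // win_len, n_windows - 1)
        beat = generate_beat(hr[w], rwat[w], ampl[w], fs)
        n = len(beat)
        if cursor + n > rec_len:
            break
        ppg[cursor : cursor + n] = beat
        peak_off = int(np.argmax(beat))
        peak_idx = cursor + peak_off
        w_peak = min(peak_idx // win_len, n_windows - 1)
        peak_sbp = sbp[w_peak]
        dbp = peak_sbp - 40.0
        abp[cursor : cursor + n] = dbp + (peak_sbp - dbp) * beat / beat.max()
        r_idx = peak_idx - int(round(pat_delay * fs))
        if r_idx - 3 * spike_half >= 0 and r_idx + 3 * spike_half + 1 <= rec_len:
            ecg[r_idx - 3 * spike_half : r_idx + 3 * spike_half + 1] += spike
        cursor += n
    # trailing partial beat region: hold last baseline values (flat tail)
    if cursor < rec_len:
        abp[cursor:] = abp[cursor - 1] if cursor > 0 else sbp[-1] - 40.0
    return ppg, abp, ecg


# ---------------------------------------------------------------------------
# Artifact injection (dropouts, noise bursts, wander, amplitude jumps)
# ---------------------------------------------------------------------------

def inject_artifacts(record: SignalRecord, noise: NoiseConfig, seed: int = 0) -> SignalRecord:
    """Corrupt the PPG channel of a record; returns a new record.

    Adds, in order: sinusoidal baseline wander (< 0.5 Hz), white noise, step
    changes in amplitude at Poisson event times, and zeroed dropout gaps
    (applied last, so gaps are runs of exact zeros).  The input record is
    not modified.
    """
    if "PPG" not in record.channels:
        raise KeyError("record has no PPG channel")
    rng = np.random.default_rng(seed)
    channels = {k: v.copy() for k, v in record.channels.items()}
    x = channels["PPG"]
    n = len(x)
    fs = record.fs
    duration_min = n / fs / 60.0
    ptp = float(np.ptp(x)) or 1.0
    t = np.arange(n) / fs

    if noise.baseline_wander_amp > 0:
        f = rng.uniform(0.1, 0.4)
        phase = rng.uniform(0, 2 * np.pi)
        x += noise.baseline_wander_amp * ptp * np.sin(2 * np.pi * f * t + phase)
    if noise.hf_noise_sd > 0:
        x += rng.normal(0.0, noise.hf_noise_sd * ptp, size=n)
    if noise.amplitude_jump_rate > 0:
        n_jumps = rng.poisson(noise.amplitude_jump_rate * duration_min)
        starts = np.sort(rng.integers(0, n, size=n_jumps))
        for s in starts:
            x[s:] *= rng.uniform(0.4, 2.5)
    if noise.dropout_rate > 0:
        n_gaps = rng.poisson(noise.dropout_rate * duration_min)
        for _ in range(n_gaps):
            gap = int(rng.uniform(0.5, 2.0) * fs)
            s = int(rng.integers(0, max(1, n - gap)))
            x[s : s + gap] = 0.0

    channels["PPG"] = x
    return SignalRecord(
        patient_id=record.patient_id,
        record_id=record.record_id,
        channels=channels,
        fs=record.fs,
        demographics=record.demographics,
        posture=record.posture,
        t0_s=record.t0_s,
        original_fs=record.original_fs,
    )
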