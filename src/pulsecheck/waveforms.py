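"""Waveform data model, format readers, windowing and window-level labels.

A :class:`SignalRecord` holds the synchronously sampled channels of one
patient-record (PPG in arbitrary units, ABP in mmHg, ECG in mV).  Records are
cut into fixed-length :class:`Window` objects, and window-level labels (SBP in
mmHg, HR in bpm, RWAT in s) are derived from the co-recorded reference
channels.

Conventions
-----------
* Sample indices are 0-based; a window is the half-open slice
  ``[start_index, start_index + len)`` in samples.
* The canonical internal sampling rate is 125 Hz; readers polyphase-resample
  other rates and keep the original rate in ``SignalRecord.original_fs``.
* Windows containing any non-finite sample in the label channel receive no
  label for the affected target and are flagged, never silently zeroed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

__all__ = [
    "CANONICAL_FS",
    "SignalRecord",
    "SegmentationSpec",
    "Window",
    "Cohort",
    "read_wfdb_record",
    "read_table_record",
    "segment",
    "derive_labels",
    "windows_to_frame",
    "export_windows_csv",
]

logger = logging.getLogger(__name__)

#: Canonical internal sampling rate, Hz.  A 2-s window at this rate has 250
#: samples, the scale at which the multi-valued-mapping thresholds are stated.
CANONICAL_FS = 125.0

# Canonical channel-name mapping used by the WFDB reader.
_CHANNEL_ALIASES = {
    "PLETH": "PPG",
    "PPG": "PPG",
    "ABP": "ABP",
    "ART": "ABP",
    "ECG": "ECG",
    "II": "ECG",
    "I": "ECG",
    "V": "ECG",
    "MCL1": "ECG",
}


class FormatError(ValueError):
    """Raised when an on-disk record cannot be parsed."""


class UnsupportedRecordError(ValueError):
    """Raised when a record contains none of the recognized channels."""


@dataclass
class SignalRecord:
    """One patient-record: named channels sharing a sampling rate.

    Parameters
    ----------
    patient_id, record_id
        Provenance identifiers; the pair is unique within a cohort.
    channels
        Map of canonical channel name (``PPG``/``ABP``/``ECG``) to a 1-D
        float array.  All channels share ``fs`` and length.
    fs
        Sampling rate, Hz.
    demographics
        Optional ``{"age": years, "height": cm, "weight": kg}``.
    posture
        Optional posture tag (``"sitting"``, ``"supine"``, ...).
    t0_s
        Record start time in seconds on the patient's own clock; used to
        place multi-record cohorts on a common time axis (calibration decay).
    original_fs
        Acquisition rate before resampling to the canonical rate, if any.
    """

    patient_id: str
    record_id: str
    channels: Dict[str, np.ndarray]
    fs: float
    demographics: Optional[Dict[str, float]] = None
    posture: Optional[str] = None
    t0_s: float = 0.0
    original_fs: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channels:
            raise ValueError("record needs at least one channel")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels differ in length: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SegmentationSpec:
    """How to cut a record channel into windows.

    ``overlap_s`` must satisfy ``0 <= overlap_s < window_s``; consecutive
    windows start ``window_s - overlap_s`` seconds apart.
    """

    window_s: float
    overlap_s: float = 0.0
    channel: str = "PPG"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_s < self.window_s):
            raise ValueError("require 0 <= overlap_s < window_s")

    @property
    def stride_s(self) -> float:
        return self.window_s - self.overlap_s


@dataclass
class Window:
    """A fixed-length excerpt of one channel with attached labels."""

    patient_id: str
    record_id: str
    start_index: int
    values: np.ndarray
    fs: float
    channel: str = "PPG"
    labels: Dict[str, float] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start_s(self) -> float:
        """Window start on the patient clock, seconds."""
        return self.t0_s + self.start_index / self.fs

    @property
    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


@dataclass
class Cohort:
    """A non-empty list of records with unique (patient_id, record_id)."""

    records: List[SignalRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must be non-empty")
        keys = [(r.patient_id, r.record_id) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (patient_id, record_id) in cohort")

    @property
    def patient_ids(self) -> List[str]:
        out: List[str] = []
        for r in self.records:
            if r.patient_id not in out:
                out.append(r.patient_id)
        return out


# ---------------------------------------------------------------------------
# WFDB reading (header + signal pair, formats 16 and 80)
# ---------------------------------------------------------------------------

def _parse_wfdb_header(header_path: Path):
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty WFDB header: {header_path}")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}")
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        toks = ln.split()
        if len(toks) < 2:
            raise FormatError(f"malformed WFDB signal line: {ln!r}")
        fname = toks[0]
        fmt = int(re.match(r"(-?\d+)", toks[1]).group(1))
        gain, baseline, units = 200.0, 0, "adu"
        if len(toks) > 2:
            m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/(\S+))?", toks[2])
            if m:
                gain = float(m.group(1)) or 200.0
                baseline = int(m.group(2)) if m.group(2) else 0
                if m.group(3):
                    units = m.group(3)
        # adc resolution/zero fields may follow; description is the tail.
        desc = toks[8] if len(toks) > 8 else (toks[-1] if len(toks) > 4 else f"sig{len(signals)}")
        signals.append(
            dict(file=fname, fmt=fmt, gain=gain, baseline=baseline, units=units, desc=desc)
        )
    return record_name, n_sig, fs, n_samples, signals


def _decode_signal(data: bytes, fmt: int, n_sig: int) -> np.ndarray:
    if fmt == 16:
        raw = np.frombuffer(data, dtype="<i2")
    elif fmt == 80:
        raw = np.frombuffer(data, dtype=np.uint8).astype(np.int16) - 128
    else:
        raise FormatError(f"unsupported WFDB signal format {fmt}")
    usable = (len(raw) // n_sig) * n_sig
    return raw[:usable].reshape(-1, n_sig)


def _ids_from_record_name(name: str):
    # MIMIC-II waveform convention: <patient>_<record>, e.g. 3141595_0001.
    parts = name.split("_", 1)
    if len(parts) == 2:
        return parts[0], name
    m = re.match(r"([a-zA-Z]*\d+)[-_]?(.*)", name)
    if m and m.group(2):
        return m.group(1), name
    return name, name


def read_wfdb_record(path, canonical_fs: float = CANONICAL_FS) -> SignalRecord:
    """Read a WFDB header + signal file pair into a :class:`SignalRecord`.

    ``path`` may point at the ``.hea`` file or at the record base name.
    Channel descriptions are mapped to canonical names (PLETH -> PPG,
    ABP/ART -> ABP, II/ECG leads -> ECG); unrecognized channels are dropped.
    Digital values are converted to physical units via the per-signal gain
    and baseline.  Records not at ``canonical_fs`` are polyphase-resampled.
    """
    path = Path(path)
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header.exists():
        raise FormatError(f"missing WFDB header: {header}")
    record_name, n_sig, fs, n_samples, signals = _parse_wfdb_header(header)

    # All MIMIC-II waveform signals of one record live in one .dat file.
    by_file: Dict[str, List[int]] = {}
    for i, sig in enumerate(signals):
        by_file.setdefault(sig["file"], []).append(i)

    channels: Dict[str, np.ndarray] = {}
    for fname, idxs in by_file.items():
        dat = header.parent / fname
        if not dat.exists():
            raise FormatError(f"missing WFDB signal file: {dat}")
        fmt = signals[idxs[0]]["fmt"]
        matrix = _decode_signal(dat.read_bytes(), fmt, len(idxs))
        for col, i in enumerate(idxs):
            sig = signals[i]
            name = _CHANNEL_ALIASES.get(sig["desc"].upper())
            if name is None or name in channels:
                continue
            values = (matrix[:, col].astype(float) - sig["baseline"]) / sig["gain"]
            channels[name] = values
    if not channels:
        raise UnsupportedRecordError(
            f"no recognized PPG/ABP/ECG channel in {header.name}"
        )

    patient_id, record_id = _ids_from_record_name(record_name)
    original_fs = None
    if not math.isclose(fs, canonical_fs):
        channels = {k: _resample(v, fs, canonical_fs) for k, v in channels.items()}
        original_fs, fs = fs, canonical_fs
    return SignalRecord(
        patient_id=patient_id,
        record_id=record_id,
        channels=channels,
        fs=fs,
        original_fs=original_fs,
    )


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    # rational approximation with a bounded denominator for the polyphase
    from fractions import Fraction

    f = Fraction(fs_out / fs_in).limit_denominator(1000)
    return resample_poly(x, f.numerator, f.denominator)


# ---------------------------------------------------------------------------
# Delimited-table reading (Aurora-BP sample-data layout)
# ---------------------------------------------------------------------------

def read_table_record(
    path,
    schema: Mapping[str, str],
    fs: Optional[float] = None,
    patient_id: Optional[str] = None,
    record_id: Optional[str] = None,
    canonical_fs: float = CANONICAL_FS,
    jitter_tol: float = 0.10,
    **meta,
) -> SignalRecord:
    """Read a delimited text file with a time column and signal columns.

    ``schema`` maps column names to channel roles and must contain a ``"t"``
    (time, seconds) entry, e.g. ``{"t": "t", "ppg": "PPG", "ekg": "ECG"}``
    where keys are file columns and values are canonical channel names.

    The time column must be strictly increasing and regularly sampled:
    deviations of the sample period beyond ``jitter_tol`` (fraction of the
    median period) raise a ``ValueError``.  The sampling rate is inferred
    from the time column when ``fs`` is not given; records are resampled to
    ``canonical_fs``.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    time_col = next((c for c, role in schema.items() if role in {"t", "time"}), None)
    if time_col is None or time_col not in df.columns:
        raise ValueError("schema must map a time column present in the file")
    t = df[time_col].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError("need at least two samples")
    if np.any(dt <= 0):
        raise ValueError("non-monotone or duplicated timestamps: irregular sampling")
    period = float(np.median(dt))
    if np.any(np.abs(dt - period) > jitter_tol * period):
        raise ValueError("timestamp jitter exceeds 10% of the sample period")
    inferred_fs = 1.0 / period
    fs_in = fs if fs is not None else inferred_fs
    if fs is not None and abs(inferred_fs - fs) > jitter_tol * fs:
        raise ValueError(
            f"declared fs {fs} Hz inconsistent with timestamps ({inferred_fs:.3g} Hz)"
        )

    channels: Dict[str, np.ndarray] = {}
    for col, role in schema.items():
        if role in {"t", "time"}:
            continue
        if col not in df.columns:
            raise ValueError(f"schema column {col!r} not in file")
        channels[role] = df[col].to_numpy(dtype=float)
    if not channels:
        raise UnsupportedRecordError("no signal columns in schema")

    original_fs = None
    out_fs = fs_in
    if not math.isclose(fs_in, canonical_fs, rel_tol=1e-9):
        channels = {k: _resample(v, fs_in, canonical_fs) for k, v in channels.items()}
        original_fs, out_fs = fs_in, canonical_fs
    return SignalRecord(
        patient_id=patient_id or path.stem,
        record_id=record_id or path.stem,
        channels=channels,
        fs=out_fs,
        original_fs=original_fs,
        **meta,
    )


# ---------------------------------------------------------------------------
# Windowing and labels
# ---------------------------------------------------------------------------

def segment(record: SignalRecord, spec: SegmentationSpec) -> List[Window]:
    """Cut one channel of a record into fixed-length windows.

    Windows start every ``window_s - overlap_s`` seconds; a trailing partial
    window is dropped.  A record shorter than one window yields an empty list
    (with a logged warning), not an error.
    """
    if spec.channel not in record.channels:
        raise KeyError(f"record has no channel {spec.channel!r}")
    n = record.n_samples
    win = int(round(spec.window_s * record.fs))
    stride = int(round(spec.stride_s * record.fs))
    if n < win:
        logger.warning(
            "record %s/%s shorter than one window (%.3g s < %.3g s)",
            record.patient_id, record.record_id, record.duration_s, spec.window_s,
        )
        return []
    x = record.channels[spec.channel]
    out = []
    for start in range(0, n - win + 1, stride):
        out.append(
            Window(
                patient_id=record.patient_id,
                record_id=record.record_id,
                start_index=start,
                values=x[start : start + win].copy(),
                fs=record.fs,
                channel=spec.channel,
                t0_s=record.t0_s,
            )
        )
    return out


def derive_labels(
    record: SignalRecord,
    windows: Sequence[Window],
    targets: Iterable[str],
    rwat_lookup: Optional[Mapping[int, float]] = None,
) -> List[Window]:
    """Attach window-level labels derived from the record's reference channels.

    * ``SBP`` — mean amplitude of ABP systolic peaks inside the window, mmHg.
    * ``HR`` — 60 / median inter-beat interval, bpm; beats come from ECG
      R-peaks when an ECG channel is present, else from PPG systolic peaks.
    * ``RWAT`` — looked up from ``rwat_lookup`` (start_index -> seconds);
      reflected-wave timing has no independent reference channel here.

    Windows whose label-channel excerpt contains non-finite samples, or in
    which no beats are found, get no label for that target and are flagged.
    Returns new Window objects; the input windows are not modified.
    """
    from .ppg_features import detect_beats, detect_r_peaks  # local: avoid cycle

    targets = set(targets)
    out: List[Window] = []

    # Detect beats once on the full record (non-finite stretches zeroed for
    # detection; affected windows are excluded per-window below).
    abp_peaks = None
    if "SBP" in targets and "ABP" in record.channels:
        abp = record.channels["ABP"]
        abp_peaks = detect_beats(np.where(np.isfinite(abp), abp, 0.0), record.fs).indices
    hr_channel = None
    hr_beats = None
    if "HR" in targets:
        if "ECG" in record.channels:
            hr_channel = "ECG"
            ecg = record.channels["ECG"]
            hr_beats = detect_r_peaks(np.where(np.isfinite(ecg), ecg, 0.0), record.fs).indices
        elif "PPG" in record.channels:
            hr_channel = "PPG"
            ppg = record.channels["PPG"]
            hr_beats = detect_beats(np.where(np.isfinite(ppg), ppg, 0.0), record.fs).indices

    for w in windows:
        labels = dict(w.labels)
        flags = list(w.flags)
        lo, hi = w.start_index, w.start_index + len(w)

        if "SBP" in targets:
            sbp = _window_sbp(record, lo, hi, abp_peaks)
            if sbp is None:
                flags.append("SBP_unlabeled")
            else:
                labels["SBP"] = sbp
        if "HR" in targets:
            hr = _window_hr(record, lo, hi, hr_channel, hr_beats)
            if hr is None:
                flags.append("HR_unlabeled")
            else:
                labels["HR"] = hr
        if "RWAT" in targets:
            if rwat_lookup is not None and w.start_index in rwat_lookup:
                labels["RWAT"] = float(rwat_lookup[w.start_index])
            else:
                flags.append("RWAT_unlabeled")
        out.append(replace(w, labels=labels, flags=flags))
    return out


def _window_sbp(record, lo, hi, abp_peaks):
    if "ABP" not in record.channels or abp_peaks is None:
        return None
    abp = record.channels["ABP"][lo:hi]
    if not np.all(np.isfinite(abp)):
        return None
    peaks = abp_peaks[(abp_peaks >= lo) & (abp_peaks < hi)]
    if len(peaks) == 0:
        return None
    return float(np.mean(record.channels["ABP"][peaks]))


def _window_hr(record, lo, hi, channel, beats):
    if channel is None or beats is None:
        return None
    seg = record.channels[channel][lo:hi]
    if not np.all(np.isfinite(seg)):
        return None
    inwin = beats[(beats >= lo) & (beats < hi)]
    if len(inwin) < 2:
        return None
    ibi = np.diff(inwin) / record.fs
    return float(60.0 / np.median(ibi))


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def windows_to_frame(windows: Sequence[Window], include_values: bool = False) -> pd.DataFrame:
    """Window/label table: one row per window with provenance and labels."""
    rows = []
    for w in windows:
        row = {
            "patient_id": w.patient_id,
            "record_id": w.record_id,
            "start_index": w.start_index,
            "fs": w.fs,
            "channel": w.channel,
        }
        row.update(w.labels)
        if include_values:
            for i, v in enumerate(w.values):
                row[f"s{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def export_windows_csv(windows: Sequence[Window], path, include_values: bool = False) -> None:
    windows_to_frame(windows, include_values=include_values).to_csv(path, index=False)
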