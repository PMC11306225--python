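"""Shared fixtures: small seeded synthetic cohorts and a WFDB fixture writer."""

from pathlib import Path

import numpy as np
import pytest

from pulsecheck import SegmentationSpec, derive_labels, segment
from pulsecheck.synthgen import ScenarioConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Well-conditioned clean cohort: 4 patients x 2 records x 2 min."""
    cfg = ScenarioConfig(n_patients=4, records_per_patient=2, record_s=120.0, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def labeled_windows(clean_cohort):
    """2-s non-overlapping PPG windows with SBP and HR labels."""
    cohort, _ = clean_cohort
    windows = []
    for rec in cohort.records:
        ws = segment(rec, SegmentationSpec(2.0, 0.0, "PPG"))
        windows.extend(derive_labels(rec, ws, ("SBP", "HR")))
    return windows


def write_wfdb_fixture(record, directory: Path, gain: float = 200.0) -> Path:
    """Write a synthetic WFDB header + format-16 signal pair for round-trip
    tests (test-local helper; the package itself does not write WFDB)."""
    directory.mkdir(parents=True, exist_ok=True)
    name = f"{record.patient_id}_{record.record_id.split('_')[-1]}".replace("R", "")
    units = {"PPG": "mV", "ABP": "mmHg", "ECG": "mV"}
    desc = {"PPG": "PLETH", "ABP": "ABP", "ECG": "II"}
    chans = list(record.channels)
    n = record.n_samples
    dig = np.empty((n, len(chans)), dtype="<i2")
    for c, ch in enumerate(chans):
        dig[:, c] = np.clip(np.round(record.channels[ch] * gain), -32768, 32767)
    (directory / f"{name}.dat").write_bytes(dig.tobytes())
    lines = [f"{name} {len(chans)} {record.fs:g} {n}"]
    for ch in chans:
        lines.append(f"{name}.dat 16 {gain:g}(0)/{units[ch]} 16 0 0 0 0 {desc[ch]}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / f"{name}.hea"
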