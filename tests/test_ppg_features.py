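"""Beat detection, handcrafted pulse-wave features, autoencoder featurizer."""

import numpy as np
import pandas as pd
import pytest

from pulsecheck import SegmentationSpec, Window, segment
from pulsecheck.ppg_features import (
    AutoencoderConfig,
    BeatSet,
    delta_and_std_features,
    detect_beats,
    detect_r_peaks,
    encode,
    extract_features,
    fit_autoencoder,
    heart_rate,
    quality_score,
    rpat,
    sdnn,
    systolic_ramp,
)
from pulsecheck.synthgen import NoiseConfig, ScenarioConfig, generate_beat, generate_cohort

FS = 125.0


def _ppg(hr=60.0, duration_s=10.0, rwat=0.25, amp=1.0):
    beat = generate_beat(hr, rwat, amp, FS)
    n = int(duration_s * FS)
    return np.tile(beat, int(np.ceil(n / len(beat))))[:n]


def _beats(intervals_s, fs=1000.0):
    # fs=1000 so sub-sample-free interval arithmetic stays exact
    idx = np.round(np.cumsum([0] + list(np.asarray(intervals_s) * fs))).astype(int)
    return BeatSet("PPG", idx, fs)


class TestDetectBeats:
    def test_clean_sixty_bpm_ten_seconds(self):
        bs = detect_beats(_ppg(60.0, 10.0), FS)
        assert 9 <= len(bs) <= 11
        np.testing.assert_allclose(bs.intervals(), 1.0, atol=0.02)

    def test_flatline_gives_empty_beats(self):
        assert len(detect_beats(np.zeros(1250), FS)) == 0

    def test_beats_match_truth_on_artifact_injected_signal(self):
        from pulsecheck.preprocess import bandpass
        from pulsecheck.synthgen import inject_artifacts

        cfg = ScenarioConfig(n_patients=1, records_per_patient=1, record_s=120, seed=21)
        cohort, _ = generate_cohort(cfg)
        rec = cohort.records[0]
        true_beats = detect_beats(rec.channels["PPG"], FS).indices
        noisy = inject_artifacts(rec, NoiseConfig(), seed=2)
        got = detect_beats(bandpass(noisy.channels["PPG"], FS), FS).indices
        tol = int(0.05 * FS)
        matched = sum(np.min(np.abs(got - b)) <= tol for b in true_beats if len(got))
        assert matched / len(true_beats) >= 0.90


class TestIntervalFeatures:
    def test_heart_rate_from_constant_intervals(self):
        assert heart_rate(_beats([0.75, 0.75, 0.75])) == pytest.approx(80.0)

    def test_heart_rate_uses_median_interval(self):
        assert heart_rate(_beats([0.5, 1.0, 0.5])) == pytest.approx(120.0)

    def test_heart_rate_missing_below_two_beats(self):
        assert heart_rate(BeatSet("PPG", [100], FS)) is None

    def test_sdnn_zero_for_constant_intervals(self):
        assert sdnn(_beats([0.8] * 5)) == pytest.approx(0.0, abs=1e-9)

    def test_sdnn_hand_computed_population_sd(self):
        # intervals 0.7, 0.8, 0.9 s -> population SD sqrt(0.02/3) = 0.0816 s
        got = sdnn(_beats([0.7, 0.8, 0.9]))
        assert got == pytest.approx(0.0816, abs=0.002)

    def test_sdnn_scales_linearly_with_intervals(self):
        a = sdnn(_beats([0.5, 0.6, 0.7]))
        b = sdnn(_beats([1.0, 1.2, 1.4]))
        assert b == pytest.approx(2 * a, rel=0.02)

    def test_sdnn_missing_below_three_beats(self):
        assert sdnn(_beats([0.8])) is None


class TestQualityScore:
    def _win(self, values):
        return Window("P0", "R0", 0, values, FS)

    def test_clean_periodic_window_scores_high(self):
        assert quality_score(self._win(_ppg(75.0, 2.0))) >= 0.9

    def test_dropout_pulls_score_down(self):
        clean = _ppg(75.0, 4.0)
        dropped = clean.copy()
        dropped[: len(dropped) // 2] = 0.0
        assert quality_score(self._win(clean)) - quality_score(self._win(dropped)) >= 0.15

    def test_flatline_scores_zero(self):
        assert quality_score(self._win(np.zeros(250))) == 0.0


class TestSystolicRamp:
    def test_triangle_beat_hand_value(self):
        # rise 0 -> 1 over 0.2 s, fall back over the rest of a 1-s beat
        one = np.concatenate(
            [np.linspace(0, 1, 26)[1:], np.linspace(1, 0, 101)[1:]]
        )  # 125 samples
        x = np.tile(one, 4)
        w = Window("P0", "R0", 0, x, FS)
        beats = detect_beats(x, FS)
        got = systolic_ramp(w, beats)
        # ramp (1-0)/0.2 = 5 a.u./s, x beat duration 1 s -> 5
        assert got == pytest.approx(5.0, rel=0.05)

    def test_amplitude_homogeneity(self):
        x = _ppg(75.0, 4.0)
        w1 = Window("P0", "R0", 0, x, FS)
        w2 = Window("P0", "R0", 0, 2 * x, FS)
        assert systolic_ramp(w2) == pytest.approx(2 * systolic_ramp(w1), rel=1e-6)

    def test_missing_without_complete_beat(self):
        assert systolic_ramp(Window("P0", "R0", 0, np.zeros(250), FS)) is None

    def test_rise_time_group_ordering(self):
        # steeper configured rise -> larger normalized dp/dt, same hr/amp
        vals = []
        for rise in (0.05, 0.08, 0.12):
            beat = generate_beat(75.0, 0.25, 1.0, FS, rise_frac=rise)
            x = np.tile(beat, 8)
            vals.append(systolic_ramp(Window("P0", "R0", 0, x, FS)))
        assert vals[0] > vals[1] > vals[2]


class TestRpat:
    def test_configured_delay_recovered(self, clean_cohort):
        cohort, truth = clean_cohort
        rec = cohort.records[0]
        ppg_beats = detect_beats(rec.channels["PPG"], FS)
        ecg_beats = detect_r_peaks(rec.channels["ECG"], FS)
        got = rpat(ecg_beats, ppg_beats)
        true_pat = truth.record_rows(rec.patient_id, rec.record_id).pat.iloc[0]
        assert got == pytest.approx(true_pat, abs=0.01)

    def test_missing_when_r_peaks_all_after_ppg(self):
        ppg = BeatSet("PPG", [100, 200], FS)
        ecg = BeatSet("ECG", [300, 400], FS)
        assert rpat(ecg, ppg) is None

    def test_inverse_pat(self):
        ecg = BeatSet("ECG", [0, 125], FS)
        ppg = BeatSet("PPG", [31, 156], FS)  # delay ~0.25 s
        r = rpat(ecg, ppg)
        assert 1.0 / r == pytest.approx(4.0, rel=0.02)


class TestDeltaAndStd:
    def _table(self):
        rows = []
        for pid, off in (("P0", 0.0), ("P1", 10.0)):
            for k in range(40):
                rows.append(
                    dict(patient_id=pid, record_id=f"{pid}_R1", start_index=250 * k,
                         HR=70.0 + off, Quality=1.0)
                )
        return pd.DataFrame(rows)

    def _baseline(self):
        return pd.DataFrame(
            [dict(patient_id="P0", HR=70.0, Quality=1.0),
             dict(patient_id="P1", HR=70.0, Quality=1.0)]
        )

    def test_delta_zero_when_equal_to_baseline(self):
        out = delta_and_std_features(self._table(), self._baseline(), ["HR"])
        assert np.allclose(out[out.patient_id == "P0"].delta_HR, 0.0)

    def test_posture_offset_recovered_in_delta(self):
        out = delta_and_std_features(self._table(), self._baseline(), ["HR"])
        assert np.allclose(out[out.patient_id == "P1"].delta_HR, 10.0, atol=1.0)

    def test_std_zero_for_constant_feature(self):
        out = delta_and_std_features(self._table(), self._baseline(), ["HR"])
        assert np.nanmax(out.std_HR.to_numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_missing_baseline_subject_gets_nan_delta(self):
        base = self._baseline().iloc[:1]
        out = delta_and_std_features(self._table(), base, ["HR"])
        assert out[out.patient_id == "P1"].delta_HR.isna().all()


class TestFeatureTable:
    def test_clean_cohort_recovers_hr_and_rpat(self, clean_cohort):
        cohort, truth = clean_cohort
        frames = []
        for rec in cohort.records:
            frames.append(extract_features(rec))
        ft = pd.concat(frames).merge(
            truth.frame, on=["patient_id", "record_id", "start_index"]
        )
        hr_ok = np.abs(ft.HR - ft.hr) <= 1.0
        pat_ok = np.abs(ft.rPAT - ft.pat) <= 0.010
        assert hr_ok.mean() >= 0.95
        assert pat_ok.mean() >= 0.95

    def test_failures_flagged_never_silent(self, clean_cohort):
        cohort, _ = clean_cohort
        rec = cohort.records[0]
        flat = rec.channels["PPG"].copy()
        flat[:] = 0.0
        from pulsecheck import SignalRecord

        rec2 = SignalRecord("PX", "PX_R0", {"PPG": flat}, FS)
        ft = extract_features(rec2, apply_bandpass=False)
        assert ft.HR.isna().all()
        assert ft.qc_flags.str.contains("HR_missing").all()


@pytest.fixture(scope="module")
def synth_windows():
    cfg = ScenarioConfig(n_patients=4, records_per_patient=2, record_s=260, seed=13)
    cohort, truth = generate_cohort(cfg)
    wins, hrs = [], []
    tf = truth.frame.set_index(["patient_id", "record_id", "start_index"])
    for rec in cohort.records:
        for w in segment(rec, SegmentationSpec(2.0, 0.0, "PPG")):
            wins.append(w)
            hrs.append(tf.loc[(w.patient_id, w.record_id, w.start_index)].hr)
    return wins, np.asarray(hrs)


class TestAutoencoder:
    def test_identical_windows_collapse(self):
        X = np.tile(_ppg(75.0, 2.0), (600, 1))
        ae = fit_autoencoder(X, AutoencoderConfig(seed=0, max_epochs=30))
        emb = encode(ae, X)
        assert ae.final_loss < 0.1
        assert np.allclose(emb, emb[0])

    def test_training_loss_reaches_target_on_clean_windows(self, synth_windows):
        wins, _ = synth_windows
        assert len(wins) >= 1000
        ae = fit_autoencoder(wins, AutoencoderConfig(seed=0))
        assert ae.converged and ae.final_loss < 0.1

    def test_embeddings_carry_heart_rate(self):
        # beat-aligned windows: with the phase nuisance removed, the
        # bottleneck embedding nearly determines HR
        from pulsecheck.infotheory import MIConfig, info_fraction

        cfg = ScenarioConfig(n_patients=4, records_per_patient=2, record_s=260, seed=13)
        cohort, truth = generate_cohort(cfg)
        wins, hrs = [], []
        for rec in cohort.records:
            tf = truth.record_rows(rec.patient_id, rec.record_id)
            beats = detect_beats(rec.channels["PPG"], rec.fs).indices
            for b in beats:
                if b + 250 > rec.n_samples:
                    continue
                wins.append(Window(rec.patient_id, rec.record_id, int(b),
                                   rec.channels["PPG"][b : b + 250], rec.fs))
                hrs.append(tf.hr[min(b // 250, len(tf) - 1)])
        ae = fit_autoencoder(wins, AutoencoderConfig(seed=0))
        emb = encode(ae, wins)
        est = info_fraction(emb, np.asarray(hrs), MIConfig(target_resolution=1.0))
        assert est.info_fraction >= 0.8

    def test_encode_deterministic(self, synth_windows):
        wins, _ = synth_windows
        ae = fit_autoencoder(wins[:600], AutoencoderConfig(seed=1, max_epochs=20))
        np.testing.assert_array_equal(encode(ae, wins[:50]), encode(ae, wins[:50]))


class TestInvariances:
    def test_interval_features_invariant_to_shift_and_scale(self):
        x = _ppg(80.0, 6.0)
        for tr in (lambda v: v + 5.0, lambda v: 3.0 * v, lambda v: 2.0 * v - 1.0):
            b1 = detect_beats(x, FS)
            b2 = detect_beats(tr(x), FS)
            assert heart_rate(b1) == pytest.approx(heart_rate(b2), abs=1e-9)
            assert sdnn(b1) == pytest.approx(sdnn(b2), abs=1e-9)
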