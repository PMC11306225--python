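"""Multi-valued-mapping checker: alignment, distances, pair search."""

import numpy as np
import pytest

from pulsecheck import SegmentationSpec, Window, derive_labels, segment
from pulsecheck.mvmap import (
    MvMapConfig,
    align,
    find_matches,
    normalize_per_record,
    pair_distance,
)
from pulsecheck.synthgen import ScenarioConfig, generate_cohort

FS = 125.0


def _periodic(seed, freq=None):
    rng = np.random.default_rng(seed)
    f = freq if freq is not None else rng.uniform(0.8, 2.0)
    t = np.arange(250) / FS
    return np.sin(2 * np.pi * f * t) + 0.3 * np.sin(4 * np.pi * f * t)


class TestAlign:
    def test_circular_shift_recovered_with_zero_distance(self):
        x = _periodic(0, 1.3)
        xj = np.roll(x, 10)
        shifted, lag = align(x, xj)
        assert lag == -10
        np.testing.assert_allclose(shifted, x, atol=1e-12)

    def test_identical_inputs_lag_zero(self):
        x = _periodic(1)
        _, lag = align(x, x)
        assert lag == 0

    def test_zero_variance_input_lag_zero(self):
        _, lag = align(np.ones(250), np.ones(250) * 3.0)
        assert lag == 0

    def test_lag_recovery_brute_force_over_random_shifts(self):
        rng = np.random.default_rng(5)
        exact = 0
        for k in range(100):
            x = _periodic(100 + k)
            m = int(rng.integers(-62, 63))
            _, lag = align(x, np.roll(x, m))
            exact += lag == -m
        assert exact == 100


class TestPairDistance:
    def test_identical_windows_distance_zero(self):
        x = _periodic(2)
        assert pair_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_per_sample_threshold_geometry(self):
        # constant per-sample offset sqrt(4e-3) over 250 samples -> L2 = 1.0
        x = _periodic(3)
        xj = x + np.sqrt(4e-3)
        d = pair_distance(x, xj)
        assert d == pytest.approx(1.0, abs=1e-9)
        # boundary-inclusive: exactly at threshold counts as a match
        wins = [
            Window("P0", "R0", 0, x, FS, labels={"SBP": 110.0}),
            Window("P0", "R0", 250, xj, FS, labels={"SBP": 130.0}),
        ]
        # defeat per-record normalization by prenormalizing to [0,1] jointly
        lo, hi = min(x.min(), xj.min()), max(x.max(), xj.max())
        wins[0].values = (x - lo) / (hi - lo)
        wins[1].values = (xj - lo) / (hi - lo)
        d_norm = pair_distance(wins[0].values, wins[1].values)
        rep = find_matches(wins, "SBP", MvMapConfig(input_threshold=d_norm + 1e-9))
        assert rep.n_matched == 2
        just_below = find_matches(wins, "SBP", MvMapConfig(input_threshold=d_norm * 0.999))
        assert just_below.n_matched == 0

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = rng.normal(size=250), rng.normal(size=250)
            assert pair_distance(a, b) == pytest.approx(pair_distance(b, a), abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pair_distance(np.zeros(250), np.zeros(200))


def _make_windows(values_labels, pid="P0"):
    return [
        Window(p if p else pid, "R0", 250 * i, v, FS, labels={"SBP": y})
        for i, (v, y, p) in enumerate(values_labels)
    ]


class TestFindMatches:
    def test_label_gap_below_output_threshold_no_match(self):
        x = _periodic(11)
        wins = _make_windows([(x, 120.0, None), (x.copy(), 120.0, None), (x.copy(), 121.0, None)])
        rep = find_matches(wins, "SBP", MvMapConfig())
        assert rep.n_matched == 0 and rep.match_fraction == 0.0

    def test_identical_windows_with_large_gap_both_match(self):
        x = _periodic(12)
        wins = _make_windows([(x, 110.0, None), (x.copy(), 130.0, None)])
        rep = find_matches(wins, "SBP", MvMapConfig())
        assert rep.n_matched == 2 and rep.match_fraction == 100.0
        assert rep.pairs[0].label_gap == pytest.approx(20.0)

    def test_unlabeled_windows_excluded_and_counted(self):
        x = _periodic(13)
        wins = _make_windows([(x, 110.0, None), (x.copy(), 130.0, None)])
        wins.append(Window("P0", "R0", 999, x.copy(), FS))
        rep = find_matches(wins, "SBP", MvMapConfig())
        assert rep.n_windows == 2 and rep.n_unlabeled == 1

    def test_planted_fraction_recovered(self):
        rng = np.random.default_rng(42)
        wins = []
        for i in range(800):  # unique far-apart windows
            wins.append(
                Window(f"P{i % 20:02d}", "R0", 250 * i, rng.normal(0.5, 0.15, 250), FS,
                       labels={"SBP": float(rng.uniform(100, 160))})
            )
        for d in range(100):  # 200 windows in planted duplicate pairs
            v = rng.normal(0.5, 0.15, 250)
            base = float(rng.uniform(100, 145))
            pid = f"P{d % 20:02d}"
            wins.append(Window(pid, "R0", 250 * (1000 + d), v, FS, labels={"SBP": base}))
            wins.append(
                Window(pid, "R0", 250 * (1200 + d), v.copy(), FS, labels={"SBP": base + 15.0})
            )
        rep = find_matches(wins, "SBP", MvMapConfig(scope="intra_patient"))
        assert rep.match_fraction == pytest.approx(20.0, abs=3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_prescreen_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        wins = []
        for i in range(120):
            base = _periodic(1000 * seed + i // 4)
            v = base + rng.normal(0, rng.uniform(0.0, 0.3), 250)
            wins.append(
                Window(f"P{i % 6}", f"R{i % 3}", 250 * i, v, FS,
                       labels={"SBP": float(rng.uniform(100, 150))})
            )
        for scope in ("intra_patient", "inter_patient"):
            cfg = MvMapConfig(scope=scope)
            fast = find_matches(wins, "SBP", cfg, prescreen=True)
            slow = find_matches(wins, "SBP", cfg, prescreen=False)
            assert fast.n_matched == slow.n_matched
            assert [(p.i, p.j) for p in fast.pairs] == [(p.i, p.j) for p in slow.pairs]
            assert np.allclose(
                [p.distance for p in fast.pairs], [p.distance for p in slow.pairs]
            )

    def test_scopes_partition_all_pairs(self):
        rng = np.random.default_rng(3)
        x = _periodic(30)
        wins = []
        for i in range(40):
            wins.append(
                Window(f"P{i % 4}", "R0", 250 * i, x + rng.normal(0, 0.01, 250), FS,
                       labels={"SBP": float(rng.uniform(90, 170))})
            )
        intra = find_matches(wins, "SBP", MvMapConfig(scope="intra_patient"))
        inter = find_matches(wins, "SBP", MvMapConfig(scope="inter_patient"))
        pids = [w.patient_id for w in wins]
        assert all(pids[p.i] == pids[p.j] for p in intra.pairs)
        assert all(pids[p.i] != pids[p.j] for p in inter.pairs)
        # together the two scopes see every qualifying pair exactly once
        all_rep = set((p.i, p.j) for p in intra.pairs) | set((p.i, p.j) for p in inter.pairs)
        cfg = MvMapConfig()
        expected = set()
        X = normalize_per_record(wins)
        for i in range(len(wins)):
            for j in range(i + 1, len(wins)):
                gap = abs(wins[i].labels["SBP"] - wins[j].labels["SBP"])
                if gap >= cfg.output_threshold and pair_distance(X[i], X[j]) <= 1.0:
                    expected.add((i, j))
        assert all_rep == expected

    def test_fraction_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        wins = []
        for i in range(120):
            v = _periodic(i // 3) + rng.normal(0, 0.1, 250)
            wins.append(
                Window(f"P{i % 5}", "R0", 250 * i, v, FS,
                       labels={"SBP": float(rng.uniform(95, 165))})
            )
        fr_in = [
            find_matches(wins, "SBP", MvMapConfig(input_threshold=t)).match_fraction
            for t in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a <= b for a, b in zip(fr_in[:-1], fr_in[1:]))
        fr_out = [
            find_matches(wins, "SBP", MvMapConfig(output_threshold=t)).match_fraction
            for t in (4.0, 8.0, 16.0, 32.0)
        ]
        assert all(a >= b for a, b in zip(fr_out[:-1], fr_out[1:]))


class TestConditioningContrast:
    @staticmethod
    def _cohort_windows(conditioning, latent_sd, seed=3):
        cfg = ScenarioConfig(
            n_patients=4, records_per_patient=2, record_s=240,
            conditioning=conditioning, latent_sd=latent_sd, seed=seed,
        )
        cohort, _ = generate_cohort(cfg)
        wins = []
        for rec in cohort.records:
            ws = segment(rec, SegmentationSpec(2.0, 0.0, "PPG"))
            wins += derive_labels(rec, ws, ("SBP",))
        return wins

    def test_well_conditioned_below_one_percent(self):
        rep = find_matches(self._cohort_windows("well", 0.0), "SBP", MvMapConfig())
        assert rep.match_fraction < 1.0

    def test_ill_conditioned_above_ten_percent(self):
        rep = find_matches(self._cohort_windows("ill", 20.0), "SBP", MvMapConfig())
        assert rep.match_fraction > 10.0

    def test_match_fraction_increases_with_latent_sd(self):
        fracs = [
            find_matches(self._cohort_windows("ill", sd), "SBP", MvMapConfig()).match_fraction
            for sd in (0.0, 5.0, 10.0, 20.0)
        ]
        assert all(a <= b for a, b in zip(fracs[:-1], fracs[1:]))
        assert fracs[-1] > fracs[0]

    def test_hr_task_is_well_conditioned(self):
        wins = self._cohort_windows("ill", 20.0)
        # HR labels: derive from the same records
        cfg = ScenarioConfig(
            n_patients=4, records_per_patient=2, record_s=240,
            conditioning="ill", latent_sd=20.0, seed=3,
        )
        cohort, _ = generate_cohort(cfg)
        hr_wins = []
        for rec in cohort.records:
            ws = segment(rec, SegmentationSpec(2.0, 0.0, "PPG"))
            hr_wins += derive_labels(rec, ws, ("HR",))
        rep = find_matches(hr_wins, "HR", MvMapConfig(output_threshold=8.0))
        assert rep.match_fraction < 1.0
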