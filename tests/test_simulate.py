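import numpy as np
import pytest

from oxyflow.events import detect_airflow_events, detect_desaturations
from oxyflow.preprocess import preprocess_recording
from oxyflow.signals import EventKind, severity_of
from oxyflow.simulate import (
    SEVERITY_AHI_RANGES,
    STUDY_SEVERITY_MIX,
    SimulationConfig,
    inject_artifacts,
    simulate_cohort,
    simulate_recording,
)

FAST = dict(fs_spo2=3.0, fs_airflow=5.0)


class TestDeterminism:
    def test_same_seed_identical(self):
        a = simulate_recording(SimulationConfig(target_ahi=20, seed=7, **FAST))
        b = simulate_recording(SimulationConfig(target_ahi=20, seed=7, **FAST))
        np.testing.assert_array_equal(a.recording.spo2.samples, b.recording.spo2.samples)
        np.testing.assert_array_equal(a.recording.airflow.samples, b.recording.airflow.samples)
        assert a.true_ahi == b.true_ahi

    def test_different_seeds_differ(self):
        a = simulate_recording(SimulationConfig(target_ahi=20, seed=1, **FAST))
        b = simulate_recording(SimulationConfig(target_ahi=20, seed=2, **FAST))
        assert not np.array_equal(a.recording.spo2.samples, b.recording.spo2.samples)

    def test_cohort_deterministic(self):
        cfg = SimulationConfig(**FAST)
        a = simulate_cohort(4, cfg=cfg, seed=11)
        b = simulate_cohort(4, cfg=cfg, seed=11)
        for ra, rb in zip(a, b):
            assert ra.true_ahi == rb.true_ahi
            np.testing.assert_array_equal(ra.recording.spo2.samples, rb.recording.spo2.samples)


class TestConservation:
    def test_event_count_matches_target(self):
        cfg = SimulationConfig(target_ahi=25.0, seed=3, **FAST)
        sim = simulate_recording(cfg)
        expected = round(25.0 * cfg.sleep_seconds / 3600.0)
        assert sim.truth_events.n_respiratory == expected

    def test_true_ahi_formula(self):
        cfg = SimulationConfig(target_ahi=18.0, seed=4, **FAST)
        sim = simulate_recording(cfg)
        assert sim.true_ahi == pytest.approx(
            3600.0 * sim.truth_events.n_respiratory / sim.sleep_seconds
        )
        assert sim.true_ahi == pytest.approx(18.0, abs=0.5)

    def test_durations_within_bounds(self):
        cfg = SimulationConfig(target_ahi=50.0, seed=5, **FAST)
        sim = simulate_recording(cfg)
        for ev in sim.truth_events:
            assert cfg.duration_min_s <= ev.duration_s <= cfg.duration_max_s

    def test_events_do_not_overlap(self):
        sim = simulate_recording(SimulationConfig(target_ahi=60.0, seed=6, **FAST))
        evs = list(sim.truth_events)
        for prev, nxt in zip(evs, evs[1:]):
            assert nxt.onset_s >= prev.end_s

    def test_events_inside_sleep_period(self):
        cfg = SimulationConfig(target_ahi=40.0, seed=8, **FAST)
        sim = simulate_recording(cfg)
        trt = cfg.trt_minutes * 60
        start = 0.5 * (trt - cfg.sleep_seconds)
        for ev in sim.truth_events:
            assert start <= ev.onset_s and ev.end_s <= start + cfg.sleep_seconds + 1e-6

    def test_zero_ahi_has_no_events(self):
        sim = simulate_recording(SimulationConfig(target_ahi=0.0, seed=9, **FAST))
        assert len(sim.truth_events) == 0
        assert sim.true_ahi == 0.0

    def test_infeasible_ahi_raises_with_maximum(self):
        with pytest.raises(ValueError, match="feasible"):
            simulate_recording(SimulationConfig(target_ahi=200.0, seed=1, **FAST))


class TestSignals:
    def test_spo2_quantised_and_in_range(self):
        sim = simulate_recording(SimulationConfig(target_ahi=30, seed=10, **FAST))
        s = sim.recording.spo2.samples
        assert np.all((s >= 0) & (s <= 100))
        np.testing.assert_allclose(np.round(s, 1), s)

    def test_native_rates_preserved(self):
        cfg = SimulationConfig(target_ahi=10, seed=11)
        sim = simulate_recording(cfg)
        assert sim.recording.spo2.fs == 75.0
        assert sim.recording.airflow.fs == 250.0
        assert sim.recording.spo2.duration_s == pytest.approx(cfg.trt_minutes * 60)

    def test_apnoea_fraction_respected(self):
        cfg = SimulationConfig(target_ahi=60, apnoea_fraction=1.0, seed=12, **FAST)
        sim = simulate_recording(cfg)
        assert all(e.kind == EventKind.APNEA for e in sim.truth_events)

    def test_detected_indices_increase_with_severity(self):
        odis, rdis = [], []
        for ahi in (5.0, 20.0, 45.0):
            sim = simulate_recording(SimulationConfig(target_ahi=ahi, seed=13, **FAST))
            clean, _ = preprocess_recording(sim.recording)
            hours = clean.spo2.valid_seconds / 3600
            odis.append(len(detect_desaturations(clean.spo2, 3.0)) / hours)
            rdis.append(len(detect_airflow_events(clean.airflow)) / hours)
        assert odis == sorted(odis)
        assert rdis == sorted(rdis)


class TestCohort:
    def test_constant_law(self):
        sims = simulate_cohort(3, ahi_law=12.0, cfg=SimulationConfig(**FAST), seed=0)
        for s in sims:
            assert s.true_ahi == pytest.approx(12.0, abs=0.6)

    def test_uniform_law_within_range(self):
        sims = simulate_cohort(
            8, ahi_law=("uniform", 10.0, 20.0), cfg=SimulationConfig(**FAST), seed=1
        )
        for s in sims:
            assert 9.0 <= s.true_ahi <= 21.0

    def test_mixture_law_covers_classes(self):
        sims = simulate_cohort(
            60, ahi_law=("mixture", STUDY_SEVERITY_MIX), cfg=SimulationConfig(**FAST), seed=2
        )
        classes = {int(severity_of(s.true_ahi)) for s in sims}
        assert classes >= {1, 2, 3}

    def test_mixture_ranges_match_severity_bins(self):
        for cls, (lo, hi) in enumerate(SEVERITY_AHI_RANGES[:3]):
            assert lo < hi
            assert int(severity_of(lo)) == cls

    def test_invalid_law_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(2, ahi_law=("gaussian", 1, 2), cfg=SimulationConfig(**FAST))

    def test_unique_ids(self):
        sims = simulate_cohort(5, cfg=SimulationConfig(**FAST), seed=3)
        assert len({s.recording.id for s in sims}) == 5


class TestArtifacts:
    def test_spo2_spikes_annotated_and_deep(self):
        sim = simulate_recording(SimulationConfig(target_ahi=10, seed=20, **FAST))
        rec, notes = inject_artifacts(sim.recording, "spo2_spike", 5.0, seed=1)
        assert len(notes) > 0
        assert rec.spo2.samples.min() < 50.0
        # original untouched
        assert sim.recording.spo2.samples.min() >= 50.0

    def test_airflow_dropout_flatlines(self):
        sim = simulate_recording(SimulationConfig(target_ahi=10, seed=21, **FAST))
        rec, notes = inject_artifacts(sim.recording, "airflow_dropout", 2.0, seed=2)
        assert len(notes) > 0
        note = notes[0]
        i0 = int((note["onset_s"] + 1) * rec.airflow.fs)
        i1 = int((note["onset_s"] + note["duration_s"] - 1) * rec.airflow.fs)
        assert np.all(rec.airflow.samples[i0:i1] == 0.0)

    def test_cleaning_recovers_from_artifacts(self):
        sim = simulate_recording(SimulationConfig(target_ahi=30, seed=22, **FAST))
        rec, _ = inject_artifacts(sim.recording, "spo2_spike", 5.0, seed=3)
        clean_dirty, rep = preprocess_recording(rec)
        clean_orig, _ = preprocess_recording(sim.recording)
        assert rep.accepted
        d_dirty = len(detect_desaturations(clean_dirty.spo2, 3.0))
        d_orig = len(detect_desaturations(clean_orig.spo2, 3.0))
        assert abs(d_dirty - d_orig) <= max(3, 0.15 * d_orig)

    def test_unknown_kind_rejected(self):
        sim = simulate_recording(SimulationConfig(target_ahi=5, seed=23, **FAST))
        with pytest.raises(ValueError):
            inject_artifacts(sim.recording, "nonsense", 100.0)
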