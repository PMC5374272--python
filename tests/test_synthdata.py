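import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pytest

from phenotrace import synthdata as sd
from phenotrace import trace_features as tf
from phenotrace.audio_features import frame_signal
from phenotrace.audio_features import _normalized_autocorr  # noqa: private oracle use


def _cfg(**kw):
    defaults = dict(n_participants=4, weeks=1, seed=11)
    defaults.update(kw)
    return sd.SyntheticConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw, field",
        [
            (dict(n_participants=1), "n_participants"),
            (dict(symptom_prevalence={"fatigue": 1.5}), "symptom_prevalence"),
            (dict(base_rates={"calls_out_per_day": 0.0}), "calls_out_per_day"),
            (dict(audio_params={"f0_mean": 500.0}), "f0_mean"),
            (dict(effect_sizes={("fatigue", "screen.count"): 1.0}), "screen.count"),
            (dict(event_drop_rate=1.0), "event_drop_rate"),
        ],
    )
    def test_invalid_field_named_in_error(self, kw, field):
        with pytest.raises(sd.ConfigurationError, match=field):
            _cfg(**kw)


class TestCohort:
    def test_prevalence_recovered_at_large_n(self):
        cfg = _cfg(n_participants=1000, symptom_prevalence={"fatigue": 0.5})
        cohort = sd.generate_cohort(cfg)
        k = sum(p.labels["fatigue"] for p in cohort.participants)
        sd3 = 3 * math.sqrt(1000 * 0.25)
        assert abs(k - 500) < sd3

    def test_zero_prevalence_all_absent(self):
        cfg = _cfg(n_participants=50, symptom_prevalence={"avoidance": 0.0})
        cohort = sd.generate_cohort(cfg)
        assert all(p.labels["avoidance"] == 0 for p in cohort.participants)

    def test_same_seed_identical(self):
        c1 = sd.generate_cohort(_cfg())
        c2 = sd.generate_cohort(_cfg())
        assert c1.participants == c2.participants

    def test_assessment_time_is_period_end(self):
        cfg = _cfg(weeks=2)
        cohort = sd.generate_cohort(cfg)
        assert all(p.assessment_time == 2 * sd.WEEK_S for p in cohort.participants)

    def test_growing_cohort_preserves_earlier_participants(self):
        small = sd.generate_cohort(_cfg(n_participants=4))
        large = sd.generate_cohort(_cfg(n_participants=8))
        assert small.participants == large.participants[:4]


class TestTraceStream:
    def test_no_planted_effect_streams_identical_across_labels(self):
        cfg = _cfg(effect_sizes={})
        cohort = sd.generate_cohort(cfg)
        p = cohort.participants[0]
        s_neg = sd.generate_trace_stream(p, {s: 0 for s in sd.SYMPTOMS}, cfg, cfg.seed)
        s_pos = sd.generate_trace_stream(p, {s: 1 for s in sd.SYMPTOMS}, cfg, cfg.seed)
        assert s_neg == s_pos

    def test_stationary_walker_within_jitter_bound(self, rng):
        # With a (near-)zero excursion radius, all accumulated distance is
        # positioning jitter.  Oracle: Monte-Carlo expectation of the
        # floored per-segment jitter distance under the generator's own
        # 15 m Gaussian jitter model.
        cfg = _cfg(base_rates={"km_per_day": 1e-6, "gps_interval_s": 600.0})
        cohort = sd.generate_cohort(cfg)
        p = cohort.participants[0]
        events = sd.generate_trace_stream(p, p.labels, cfg, cfg.seed)
        n_seg = sum(1 for e in events if e.kind == "gps") - 1
        jit = rng.normal(0.0, 15e-3, (20000, 2, 2))  # km, two endpoints, two coords
        seg = np.hypot(*(jit[:, 1] - jit[:, 0]).T)
        seg[seg < 0.03] = 0.0
        expected = n_seg * seg.mean()
        spread = 4 * math.sqrt(n_seg) * seg.std(ddof=1)
        assert abs(tf.travel_distance_sum(events) - expected) < spread

    def test_planted_shift_recovered_monte_carlo(self):
        # d=2 on weekly unique texting counterparties; mean difference must
        # land within 3 SEs of the generator's own planted shift.
        d = 2.0
        cfg = _cfg(
            n_participants=500,
            symptom_prevalence={"fatigue": 0.5},
            effect_sizes={("fatigue", "sms.address.count"): d},
            base_rates={"gps_interval_s": 20000.0},
        )
        cohort = sd.generate_cohort(cfg)
        vals = {0: [], 1: []}
        for p in cohort.participants:
            ev = sd.generate_trace_stream(p, p.labels, cfg, cfg.seed)
            win = tf.window_events(ev, p.assessment_time)
            vals[p.labels["fatigue"]].append(tf.sms_address_count(win))
        g0, g1 = np.array(vals[0]), np.array(vals[1])
        diff = g1.mean() - g0.mean()
        _, sigma = sd.nominal_feature_moments(cfg)["sms.address.count"]
        se = math.sqrt(g0.var(ddof=1) / len(g0) + g1.var(ddof=1) / len(g1))
        assert abs(diff - d * sigma) < 3 * se

    def test_peers_are_opaque_hashes(self, small_dataset):
        _, streams, _ = small_dataset
        peers = {e.peer for evs in streams.values() for e in evs if e.peer}
        assert all(len(p) == 16 and all(c in "0123456789abcdef" for c in p) for p in peers)


class TestWeeklyFeatureSampler:
    def test_matches_nominal_moments(self, rng):
        cfg = _cfg()
        n = 4000
        draw = sd.draw_weekly_features(rng, cfg, n)
        for feat, (mean, sigma) in sd.nominal_feature_moments(cfg).items():
            x = draw[feat].to_numpy()
            assert abs(x.mean() - mean) < 4 * sigma / math.sqrt(n), feat
            assert abs(x.std(ddof=1) - sigma) < 0.1 * sigma, feat


class TestAudioSynthesis:
    def test_constant_f0_contour(self, rng):
        _, truth = sd.synthesize_voice(rng, 200.0, 0.0, -10.0, 40.0, 2.0)
        assert truth.f0_sd == 0.0
        assert truth.f0_mean == pytest.approx(200.0)

    def test_huge_snr_approaches_noiseless(self):
        # Same seed, SNR 200 dB vs 20 dB: the voiced synthesis is identical,
        # so the residual between the two renderings is pure noise and the
        # near-noiseless rendering differs from its voiced part by nothing.
        clean, _ = sd.synthesize_voice(np.random.default_rng(5), 150.0, 10.0, -10.0, 200.0, 2.0)
        noisy, _ = sd.synthesize_voice(np.random.default_rng(5), 150.0, 10.0, -10.0, 20.0, 2.0)
        silent_gap = np.abs(clean) < 1e-10  # inter-burst silence in the clean render
        assert silent_gap.any()
        assert np.max(np.abs(clean[silent_gap])) < 1e-9  # no audible noise floor
        assert np.max(np.abs(noisy[silent_gap])) > 1e-4  # noise clearly present at 20 dB

    def test_f0_200_gives_40_sample_autocorr_lag(self):
        rng = np.random.default_rng(3)
        sig, truth = sd.synthesize_voice(rng, 200.0, 0.0, -6.0, 60.0, 2.0)
        frames = frame_signal(sig)
        energies = (frames**2).sum(axis=1)
        frame = frames[int(np.argmax(energies))]
        r = _normalized_autocorr(frame, 100)
        lag = 20 + int(np.argmax(r[20:101]))
        assert abs(lag - 40) <= 1

    def test_out_of_range_f0_rejected(self, rng):
        with pytest.raises(sd.ConfigurationError, match="f0_mean"):
            sd.synthesize_voice(rng, 50.0, 5.0, -10.0, 30.0, 1.0)

    def test_ground_truth_matches_contour_stats(self):
        cfg = _cfg()
        cohort = sd.generate_cohort(cfg)
        p = cohort.participants[0]
        diary, truth = sd.generate_audio_diary(p, p.labels, cfg, cfg.seed, 0)
        assert diary.rate == 8000
        assert diary.samples.dtype == np.int16
        assert 0.0 < truth.voiced_fraction < 1.0
        assert truth.f0_sd >= 0.0


class TestFixtureDataset:
    def test_round_trip_event_counts(self, small_dataset, tmp_path):
        cohort, streams, diaries = small_dataset
        manifest = sd.write_fixture_dataset(cohort, streams, diaries, tmp_path)
        for entry in manifest["participants"]:
            pid = entry["participant_id"]
            back = tf.read_trace_log(tmp_path / entry["trace_path"])
            assert len(back) == len(streams[pid])
            assert len(entry["recordings"]) == len(diaries[pid])

    def test_empty_cohort_valid_manifest(self, tmp_path):
        manifest = sd.write_fixture_dataset(sd.Cohort(participants=[]), {}, {}, tmp_path)
        assert manifest["participants"] == []
        assert json.loads((tmp_path / "manifest.json").read_text())["participants"] == []

    def test_fixture_directory_deterministic(self, small_dataset, tmp_path):
        cohort, streams, diaries = small_dataset

        def digest(root: Path) -> dict:
            return {
                p.relative_to(root).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(root.rglob("*"))
                if p.is_file()
            }

        sd.write_fixture_dataset(cohort, streams, diaries, tmp_path / "a")
        sd.write_fixture_dataset(cohort, streams, diaries, tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_labels_csv_schema(self, small_dataset, tmp_path):
        cohort, streams, diaries = small_dataset
        sd.write_fixture_dataset(cohort, streams, diaries, tmp_path)
        header = (tmp_path / "labels.csv").read_text().splitlines()[0]
        assert header == "participant_id,assessment_time,symptom,present"
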