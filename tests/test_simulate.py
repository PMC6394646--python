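"""Synthetic-data generator: determinism, format round-trips, signal regimes."""

import filecmp

import numpy as np
import pytest

from adlfuse.bot import read_bot_stream
from adlfuse.frame import DEFAULT_FRAME
from adlfuse.knowledge import KnowledgeProfile, parse_table
from adlfuse.sensors import window_stream
from adlfuse.simulate import (
    DEFAULT_PROFILES,
    SimConfig,
    generate_dataset,
    generate_knowledge_table,
)


def small_config(seed=5, n=6):
    return SimConfig(seed=seed, samples_per_class=n, images_per_bout=3)


class TestKnowledgeTables:
    def test_tables_cover_the_day_and_parse(self, tmp_path):
        cfg = small_config()
        for scope in ("weekday", "weekend"):
            table = generate_knowledge_table(cfg, scope)
            assert table.periods[0][0] == 0
            assert table.periods[-1][1] == 24 * 3600
            table.to_csv(tmp_path / f"k_{scope}.csv")
            back = parse_table(tmp_path / f"k_{scope}.csv", scope=scope)
            assert np.array_equal(back.scores, table.scores)
        KnowledgeProfile(
            [generate_knowledge_table(cfg, "weekday"),
             generate_knowledge_table(cfg, "weekend")]
        )

    def test_off_schedule_activity_scores_zero(self):
        cfg = small_config()
        table = generate_knowledge_table(cfg, "weekday")
        j = DEFAULT_FRAME.index("MT")  # meetings: 10-12 and 14-16 on weekdays
        scheduled = {h for s, e, wd, _ in DEFAULT_PROFILES["MT"].schedule
                     for h in range(s, e) if wd > 0}
        for h in range(24):
            if h not in scheduled:
                assert table.scores[h, j] == 0


class TestDeterminism:
    def test_same_seed_same_bundle_bytes(self, tmp_path):
        for d in ("one", "two"):
            generate_dataset(small_config()).to_files(tmp_path / d)
        for name in ("knowledge_weekday.csv", "knowledge_weekend.csv",
                     "tags.jsonl", "imu.csv", "gps.csv", "labels.csv",
                     "manifest.yaml"):
            assert filecmp.cmp(
                tmp_path / "one" / name, tmp_path / "two" / name, shallow=False
            ), name

    def test_different_seeds_differ(self):
        a = generate_dataset(small_config(seed=5))
        b = generate_dataset(small_config(seed=6))
        assert any(
            ta.tags != tb.tags for ta, tb in zip(a.all_tags(), b.all_tags())
        )


class TestBundleStructure:
    def test_counts_and_alignment(self, tiny_dataset):
        labels = tiny_dataset.labels()
        assert len(labels) == 15 * 8
        for bout in tiny_dataset.bouts:
            assert len(bout.tags) == len(bout.image_ids) == bout.image_times.size
            # IMU fully covers each image's ±1.5 s window
            assert bout.imu["time"].iloc[0] <= bout.image_times[0] - 1.5
            assert bout.imu["time"].iloc[-1] >= bout.image_times[-1] + 1.5

    def test_round_trip_through_readers(self, tiny_dataset, tmp_path):
        tiny_dataset.to_files(tmp_path)
        bots = read_bot_stream(tmp_path / "tags.jsonl")
        assert len(bots) == 15 * 8
        parse_table(tmp_path / "knowledge_weekday.csv")
        parse_table(tmp_path / "knowledge_weekend.csv")

    def test_every_bout_windowable(self, tiny_dataset):
        for bout in tiny_dataset.bouts[:10]:
            windows, skipped = window_stream(bout.imu, bout.image_times)
            assert not skipped
            assert len(windows) == bout.image_times.size


class TestSignalRegimes:
    def test_walking_has_dominant_peak_near_its_gait_frequency(self):
        ds = generate_dataset(small_config(seed=11))
        bout = next(b for b in ds.bouts if b.label == "WO")
        z = bout.imu["az"].to_numpy()
        z = z - z.mean()
        freqs = np.fft.rfftfreq(z.size, d=1 / 90.0)
        power = np.abs(np.fft.rfft(z)) ** 2
        peak = freqs[np.argmax(power)]
        assert 1.6 < peak < 2.4

    def test_sedentary_classes_share_low_variance(self):
        ds = generate_dataset(small_config(seed=11))
        stds = {}
        for label in ("CU", "TV", "RD"):
            bout = next(b for b in ds.bouts if b.label == label)
            stds[label] = bout.imu[["ax", "ay", "az"]].std().mean()
        assert all(s < 0.06 for s in stds.values())

    def test_lying_down_reorients_gravity(self):
        ds = generate_dataset(small_config(seed=11))
        bout = next(b for b in ds.bouts if b.label == "LD")
        assert bout.imu["ax"].mean() == pytest.approx(1.0, abs=0.1)
        assert abs(bout.imu["az"].mean()) < 0.2

    def test_transport_speed_regime(self):
        ds = generate_dataset(small_config(seed=11))
        speeds = [f.speed for b in ds.bouts if b.label == "TP"
                  for f in b.gps if f is not None]
        sed = [f.speed for b in ds.bouts if b.label == "TV"
               for f in b.gps if f is not None]
        assert np.median(speeds) > 5.0
        assert np.median(sed) < 0.5

    def test_gps_gaps_present_at_default_rate(self):
        ds = generate_dataset(SimConfig(seed=9, samples_per_class=20))
        fixes = [f for b in ds.bouts for f in b.gps]
        gap_rate = sum(f is None for f in fixes) / len(fixes)
        assert 0.04 < gap_rate < 0.2


class TestTagStream:
    def test_pure_signature_mixture_is_separable(self):
        from adlfuse.bot import ClassifierConfig, TagCorpus, build_classifier, classify_bot
        from adlfuse.dsmt import argmax_activity

        cfg = SimConfig(seed=13, samples_per_class=12, images_per_bout=4,
                        tag_mixture=1.0, confusion_rate=0.0)
        train = generate_dataset(cfg)
        corpus = TagCorpus.from_labeled(train.all_tags(), train.labels())
        centers = build_classifier(corpus, ClassifierConfig())
        test = generate_dataset(
            SimConfig(seed=14, samples_per_class=6, images_per_bout=3,
                      tag_mixture=1.0, confusion_rate=0.0)
        )
        correct = 0
        for bot, label in zip(test.all_tags(), test.labels()):
            bba, _ = classify_bot(bot, centers, DEFAULT_FRAME)
            correct += argmax_activity(bba) == label
        assert correct / len(test.labels()) > 0.99

    def test_pure_background_mixture_is_chance_level(self):
        from adlfuse.bot import ClassifierConfig, TagCorpus, build_classifier, classify_bot
        from adlfuse.dsmt import argmax_activity

        cfg = SimConfig(seed=15, samples_per_class=12, images_per_bout=4,
                        tag_mixture=0.0)
        train = generate_dataset(cfg)
        corpus = TagCorpus.from_labeled(train.all_tags(), train.labels())
        centers = build_classifier(corpus, ClassifierConfig())
        test = generate_dataset(
            SimConfig(seed=16, samples_per_class=20, images_per_bout=5,
                      tag_mixture=0.0)
        )
        correct = 0
        for bot, label in zip(test.all_tags(), test.labels()):
            bba, _ = classify_bot(bot, centers, DEFAULT_FRAME)
            correct += argmax_activity(bba) == label
        # 300 draws at p = 1/15: stay within a generous binomial band
        assert correct / len(test.labels()) < 0.18
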