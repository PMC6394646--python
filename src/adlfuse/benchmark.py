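"""End-to-end benchmark on the default synthetic study conditions.

Trains the tag classifier and the sensor classifier on one generated bundle,
then scores every test image four ways — knowledge alone, image alone,
sensors alone, and the full two-level fusion — against the gold labels.
This is the harness behind the package's fusion-gain and sensor-separability
checks and the `adlfuse benchmark` command.

Problem sizes default to 100 training and 60 test images per class over the
15-activity frame; the train and test bundles are generated from independent
child seeds of the benchmark seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from adlfuse.bot import ClassifierConfig, TagCorpus, build_classifier, classify_bot
from adlfuse.dsmt import BBA, argmax_activity
from adlfuse.evaluate import EvalReport, evaluate
from adlfuse.frame import Frame
from adlfuse.fusion import FusionConfig, FusionDecision, fuse_full, fuse_simplified
from adlfuse.knowledge import KnowledgeProfile, knowledge_bba
from adlfuse.sensors import (
    GpsFix,
    SensorModel,
    extract_features,
    sensor_bba,
    train_sensor_model,
    window_stream,
)
from adlfuse.simulate import SimConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

#: Reduced (C, gamma) grid used by the benchmark to keep training brisk.
BENCH_GRID = {"svc__C": [4.0, 16.0, 64.0], "svc__gamma": [0.02, 0.08, 0.33]}


@dataclass
class BenchmarkResult:
    frame: Frame
    gold: list[str]
    predictions: dict[str, list[str]]  # source -> per-sample labels
    reports: dict[str, EvalReport]
    decisions: list[FusionDecision]
    sensor_model: SensorModel

    def summary(self) -> dict[str, float]:
        out = {}
        for name, rep in self.reports.items():
            out[f"{name}_macro_f1"] = rep.macro_f1
            out[f"{name}_accuracy"] = rep.accuracy
        return out


def dataset_features(
    dataset: SyntheticDataset,
) -> tuple[np.ndarray, list[str], list, list]:
    """Window + featurize every bout.

    Returns ``(features, labels, bots, times)`` aligned per kept window;
    ``times`` are naive datetimes for the knowledge lookup.
    """
    import datetime as dt

    feats, labels, bots, times = [], [], [], []
    for bout in dataset.bouts:
        windows, skipped = window_stream(bout.imu, bout.image_times)
        if skipped:
            logger.warning("bout %s: %d windows skipped", bout.label, len(skipped))
        kept = [
            i for i, ts in enumerate(bout.image_times) if float(ts) not in skipped
        ]
        last_fix: GpsFix | None = None
        for w, i in zip(windows, kept):
            fix = bout.gps[i]
            feats.append(extract_features(w, fix, last_fix))
            if fix is not None:
                last_fix = fix
            labels.append(bout.label)
            bots.append(bout.tags[i])
            times.append(
                bout.start + dt.timedelta(seconds=i * dataset.config.image_period)
            )
    return np.asarray(feats), labels, bots, times


def run_benchmark(
    seed: int = 0,
    *,
    train_per_class: int = 100,
    test_per_class: int = 60,
    fusion: FusionConfig = FusionConfig(),
    use_knowledge: bool = True,
    bot_config: ClassifierConfig = ClassifierConfig(),
    svc_grid: dict | None = None,
) -> BenchmarkResult:
    """Generate, train, fuse, and score one benchmark replicate."""
    ss = np.random.SeedSequence(seed)
    train_seed, test_seed, model_seed = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    )
    train_cfg = SimConfig(seed=train_seed, samples_per_class=train_per_class)
    test_cfg = replace(train_cfg, seed=test_seed, samples_per_class=test_per_class)
    train = generate_dataset(train_cfg)
    test = generate_dataset(test_cfg)
    frame = train_cfg.frame

    # image source
    corpus = TagCorpus.from_labeled(train.all_tags(), train.labels())
    centers = build_classifier(corpus, bot_config)

    # sensor source
    X_train, y_train, _, _ = dataset_features(train)
    model = train_sensor_model(
        X_train, np.asarray(y_train),
        svc_grid if svc_grid is not None else BENCH_GRID,
        seed=model_seed,
    )

    # knowledge source
    profile = KnowledgeProfile([train.weekday_table, train.weekend_table])

    gold: list[str] = []
    preds: dict[str, list[str]] = {"knowledge": [], "image": [], "sensors": [], "fusion": []}
    decisions: list[FusionDecision] = []
    X_test, y_test, test_bots, test_times = dataset_features(test)
    proba = model.predict_proba(X_test)
    for k, (label, bot, when) in enumerate(zip(y_test, test_bots, test_times)):
        bba_s = _proba_to_bba(model, proba[k], frame)
        bba_i, _ = classify_bot(bot, centers, frame)
        gold.append(label)
        preds["image"].append(argmax_activity(bba_i))
        preds["sensors"].append(argmax_activity(bba_s))
        if use_knowledge:
            bba_k = knowledge_bba(profile, when)
            preds["knowledge"].append(argmax_activity(bba_k))
            decision = fuse_full(bba_k, bba_i, bba_s, fusion)
        else:
            decision = fuse_simplified(bba_i, bba_s, fusion)
        preds["fusion"].append(decision.final)
        decisions.append(decision)
    if not use_knowledge:
        preds.pop("knowledge")

    reports = {name: evaluate(p, gold, frame) for name, p in preds.items()}
    return BenchmarkResult(
        frame=frame,
        gold=gold,
        predictions=preds,
        reports=reports,
        decisions=decisions,
        sensor_model=model,
    )


def _proba_to_bba(model: SensorModel, proba: np.ndarray, frame: Frame) -> BBA:
    weights = np.zeros(len(frame))
    for c, p in zip(model.classes, proba):
        weights[frame.index(c)] = p
    from adlfuse.dsmt import make_bayesian_bba

    return make_bayesian_bba(frame, weights)
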