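"""Synthetic multisource datasets with the structure each fusion stage assumes.

No public dataset accompanies the method, so every stage is exercised on
generated data whose statistical structure mirrors what the pipeline relies
on in real recordings:

* **Tags** — each activity has a small set of signature tags (its
  "combination of objects") mixed with a shared background vocabulary of
  generic tags; a fraction of images is *visually confused*, drawing its
  signature tags from a designated partner activity (screens look alike,
  desks look alike), which makes the image source good but imperfect.
* **IMU** — five signal regimes at 90 Hz: sedentary (low-variance noise
  around gravity; deliberately identical across all sedentary activities so
  motion sensors cannot separate them), periodic (gait oscillation near a
  characteristic frequency), reoriented (gravity moved off the body's
  vertical axis, as when lying down), irregular (bursty movement), and
  vehicle (vibration plus high GPS speed).
* **GPS** — log-normal speed regimes matched to the activity, with fixes
  dropped at a configurable rate to exercise carry-forward.
* **Schedule** — every activity has clock-time affinities (0–10 scores per
  hour, weekday and weekend); bout start times are drawn from those
  affinities and the same affinities are written out as the wearer's
  knowledge tables, so the knowledge source is informative but coarse.

Each bout of an activity is placed in its own calendar week (same weekday
and clock time, shifted by whole weeks) so exported streams are strictly
ordered in time.  All sampling flows from one seed; identical seeds produce
byte-identical exports.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from adlfuse.bot import BagOfTags, write_bot_stream
from adlfuse.frame import DEFAULT_FRAME, Frame
from adlfuse.knowledge import KnowledgeTable
from adlfuse.sensors import CHANNELS, GpsFix

ImuRegime = Literal["sedentary", "periodic", "reoriented", "irregular", "vehicle"]

#: Shared background vocabulary of generic, non-discriminative tags.
BACKGROUND_TAGS = (
    "indoors", "no person", "people", "room", "table", "chair", "light",
    "wall", "floor", "furniture", "home", "daytime", "blur", "color",
    "object", "closeup", "adult", "one", "horizontal", "contemporary",
    "window", "door", "shadow", "still life",
)


@dataclass(frozen=True)
class ActivityProfile:
    """Generative description of one activity class.

    ``schedule`` rows are (start_hour, end_hour, weekday_score,
    weekend_score) with half-open hour ranges and 0–10 integer scores; hours
    outside every row score 0.
    """

    label: str
    signature_tags: tuple[str, ...]
    imu_regime: ImuRegime
    speed_mean: float  # m/s, median of the log-normal speed law
    schedule: tuple[tuple[int, int, int, int], ...]
    confusion_partner: str | None = None
    imu_freq: float = 2.0  # Hz, periodic regimes only (< 45 Hz Nyquist)
    imu_amp: float = 0.5  # g, oscillation/burst amplitude
    speed_sigma: float = 0.4  # log-space spread

    def __post_init__(self) -> None:
        if not 0 < self.imu_freq < 45.0:
            raise ValueError("imu_freq must be below the 45 Hz Nyquist limit")
        for s, e, wd, we in self.schedule:
            if not (0 <= s < e <= 24):
                raise ValueError("bad schedule hours")
            if not (0 <= wd <= 10 and 0 <= we <= 10):
                raise ValueError("schedule scores must be 0..10")


def _sig(*tags: str) -> tuple[str, ...]:
    return tags


DEFAULT_PROFILES: dict[str, ActivityProfile] = {
    "CN": ActivityProfile(
        "CN", _sig("broom", "vacuum", "dust", "spray bottle", "mop", "bucket"),
        "irregular", 0.3, ((8, 11, 4, 6), (17, 19, 3, 3)), "WU", imu_amp=0.35),
    "CU": ActivityProfile(
        "CU", _sig("keyboard", "monitor", "screen", "laptop", "mouse", "desk"),
        "sedentary", 0.03, ((9, 12, 9, 2), (13, 17, 9, 2), (20, 22, 3, 3)), "WT"),
    "ET": ActivityProfile(
        "ET", _sig("food", "plate", "fork", "meal", "dinner", "bowl"),
        "sedentary", 0.03, ((7, 9, 8, 6), (12, 13, 9, 8), (18, 20, 8, 8)), "TK"),
    "EM": ActivityProfile(
        "EM", _sig("game", "cards", "player", "dice", "board game", "screen"),
        "sedentary", 0.03, ((13, 17, 2, 8), (20, 23, 3, 6)), "TV"),
    "LD": ActivityProfile(
        "LD", _sig("bed", "pillow", "blanket", "ceiling", "lamp", "mattress"),
        "reoriented", 0.02, ((0, 7, 10, 10), (13, 14, 2, 5), (22, 24, 9, 9)), "TV"),
    "MT": ActivityProfile(
        "MT", _sig("whiteboard", "projector", "conference", "presentation",
                   "colleague", "chart"),
        "sedentary", 0.03, ((10, 12, 6, 0), (14, 16, 6, 0)), "TK"),
    "RD": ActivityProfile(
        "RD", _sig("book", "page", "text", "bookshelf", "novel", "paper"),
        "sedentary", 0.03, ((12, 14, 3, 4), (19, 23, 5, 5)), "WT"),
    "SP": ActivityProfile(
        "SP", _sig("shelf", "market", "cart", "price", "store", "merchandise"),
        "periodic", 0.7, ((10, 13, 2, 7), (17, 19, 4, 4)), "WO",
        imu_freq=1.5, imu_amp=0.25),
    "TK": ActivityProfile(
        "TK", _sig("person", "face", "conversation", "portrait", "smile",
                   "gesture"),
        "sedentary", 0.04, ((8, 23, 2, 3),), "MT"),
    "TU": ActivityProfile(
        "TU", _sig("phone", "smartphone", "hand", "call", "touchscreen",
                   "device"),
        "sedentary", 0.03, ((8, 23, 2, 2),), "TK"),
    "TP": ActivityProfile(
        "TP", _sig("dashboard", "road", "traffic", "windshield", "seat belt",
                   "steering wheel"),
        "vehicle", 11.0, ((7, 9, 6, 2), (17, 19, 6, 3)), "SP", speed_sigma=0.3),
    "WO": ActivityProfile(
        "WO", _sig("street", "tree", "sidewalk", "sky", "building", "path"),
        "periodic", 1.4, ((7, 9, 3, 2), (12, 13, 2, 2), (15, 18, 3, 7)), "SP",
        imu_freq=2.0, imu_amp=0.6, speed_sigma=0.15),
    "WU": ActivityProfile(
        "WU", _sig("sink", "faucet", "soap", "towel", "bathroom", "toothbrush"),
        "irregular", 0.05, ((6, 8, 8, 7), (22, 24, 6, 6)), "CN", imu_amp=0.3),
    "TV": ActivityProfile(
        "TV", _sig("television", "screen", "remote control", "sofa", "show",
                   "living room"),
        "sedentary", 0.02, ((19, 23, 8, 6), (13, 15, 1, 4)), "EM"),
    "WT": ActivityProfile(
        "WT", _sig("pen", "notebook", "handwriting", "desk", "paper", "ink"),
        "sedentary", 0.03, ((9, 11, 2, 3), (19, 22, 3, 3)), "CU"),
}

#: Signature-tag draw probabilities within a class (6 tags, most common first).
_SIG_PROBS = np.array([0.30, 0.20, 0.15, 0.15, 0.10, 0.10])
#: Zipf-like background tag law.
_BG_PROBS = (lambda n: (1.0 / np.arange(1, n + 1)) / (1.0 / np.arange(1, n + 1)).sum())(
    len(BACKGROUND_TAGS)
)

_WEEKDAY_BASE = dt.datetime(2024, 1, 1)  # a Monday
_WEEKEND_BASE = dt.datetime(2024, 1, 6)  # a Saturday


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic dataset."""

    seed: int
    frame: Frame = DEFAULT_FRAME
    profiles: dict[str, ActivityProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    samples_per_class: int = 100  # images per activity
    images_per_bout: int = 10
    tag_len: int = 20  # tags per image
    tag_mixture: float = 0.55  # probability a tag is signature vs background
    confusion_rate: float = 0.13  # probability an image mimics the partner
    imu_rate: float = 90.0  # Hz
    image_period: float = 4.0  # s between images
    gps_gap_rate: float = 0.1  # probability a fix is missing
    anchor_lat: float = 40.44
    anchor_lon: float = -79.95

    def __post_init__(self) -> None:
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")
        if not 0.0 <= self.tag_mixture <= 1.0:
            raise ValueError("tag_mixture must be in [0, 1]")
        missing = [l for l in self.frame.labels if l not in self.profiles]
        if missing:
            raise ValueError(f"profiles missing for {missing}")


@dataclass
class Bout:
    """One contiguous spell of an activity: images, IMU trace, GPS fixes."""

    label: str
    start: dt.datetime
    image_ids: list[str]
    image_times: np.ndarray  # epoch seconds
    tags: list[BagOfTags]
    imu: pd.DataFrame
    gps: list[GpsFix | None]  # one slot per image; None = dropped fix


@dataclass
class SyntheticDataset:
    """A complete timestamp-aligned fixture bundle."""

    config: SimConfig
    bouts: list[Bout]
    weekday_table: KnowledgeTable
    weekend_table: KnowledgeTable

    def labels(self) -> list[str]:
        return [b.label for b in self.bouts for _ in b.image_ids]

    def all_tags(self) -> list[BagOfTags]:
        return [t for b in self.bouts for t in b.tags]

    def to_files(self, outdir: str | Path) -> None:
        """Write the bundle in the package's external formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.weekday_table.to_csv(outdir / "knowledge_weekday.csv")
        self.weekend_table.to_csv(outdir / "knowledge_weekend.csv")
        write_bot_stream(self.all_tags(), outdir / "tags.jsonl")
        imu = pd.concat([b.imu for b in self.bouts], ignore_index=True)
        imu.to_csv(outdir / "imu.csv", index=False, float_format="%.6f")
        gps_rows = []
        for b in self.bouts:
            for ts, fix in zip(b.image_times, b.gps):
                if fix is not None:
                    gps_rows.append([fix.time, fix.lat, fix.lon, fix.speed])
        pd.DataFrame(gps_rows, columns=["time", "lat", "lon", "speed"]).to_csv(
            outdir / "gps.csv", index=False, float_format="%.6f"
        )
        labels = pd.DataFrame(
            [
                [iid, ts, b.label]
                for b in self.bouts
                for iid, ts in zip(b.image_ids, b.image_times)
            ],
            columns=["image_id", "time", "label"],
        )
        labels.to_csv(outdir / "labels.csv", index=False, float_format="%.3f")
        manifest = {
            "seed": self.config.seed,
            "frame": list(self.config.frame.labels),
            "samples_per_class": self.config.samples_per_class,
            "files": [
                "knowledge_weekday.csv", "knowledge_weekend.csv", "tags.jsonl",
                "imu.csv", "gps.csv", "labels.csv",
            ],
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Knowledge tables


def generate_knowledge_table(
    config: SimConfig, scope: Literal["weekday", "weekend"]
) -> KnowledgeTable:
    """Hourly time–activity table scored from the profiles' schedule
    affinities; covers 00:00–24:00."""
    scores = np.zeros((24, len(config.frame)), dtype=int)
    col = 3 if scope == "weekend" else 2
    for j, label in enumerate(config.frame.labels):
        for s, e, *vals in config.profiles[label].schedule:
            scores[s:e, j] = np.maximum(scores[s:e, j], vals[col - 2])
    periods = [(h * 3600, (h + 1) * 3600) for h in range(24)]
    labels = [f"{h:02d}:00-{h:02d}:59" for h in range(24)]
    return KnowledgeTable(
        frame=config.frame, periods=periods, scores=scores, scope=scope,
        kind="time", period_labels=labels,
    )


# ---------------------------------------------------------------------------
# Per-regime IMU synthesis


def _imu_signals(
    profile: ActivityProfile, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """6×n signal array (accel in g, gyro in °/s) for one bout."""
    n = t.size
    acc = np.zeros((3, n))
    gyr = np.zeros((3, n))
    tilt = rng.normal(0, 0.03, size=3)  # per-bout posture offset
    if profile.imu_regime == "sedentary":
        acc[2] = 1.0
        acc += rng.normal(0, 0.025, size=(3, n))
        gyr += rng.normal(0, 2.0, size=(3, n))
    elif profile.imu_regime == "reoriented":
        acc[0] = 1.0  # gravity along the body's x axis
        acc += rng.normal(0, 0.015, size=(3, n))
        gyr += rng.normal(0, 1.0, size=(3, n))
    elif profile.imu_regime == "periodic":
        f = profile.imu_freq * (1 + rng.normal(0, 0.03))
        a = profile.imu_amp
        phase = rng.uniform(0, 2 * np.pi)
        acc[2] = 1.0 + a * np.sin(2 * np.pi * f * t + phase)
        acc[0] = 0.4 * a * np.sin(2 * np.pi * f * t + phase + 0.7)
        acc[1] = 0.25 * a * np.sin(4 * np.pi * f * t + phase)
        acc += rng.normal(0, 0.05, size=(3, n))
        gyr[0] = 60 * a * np.sin(2 * np.pi * f * t + phase + 1.1)
        gyr[1] = 40 * a * np.sin(2 * np.pi * f * t + phase + 2.0)
        gyr += rng.normal(0, 5.0, size=(3, n))
    elif profile.imu_regime == "irregular":
        acc[2] = 1.0
        # bursty envelope: exponential on/off segments (~2 s / ~1.5 s)
        env = np.zeros(n)
        i, on = 0, rng.random() < 0.5
        while i < n:
            dur = max(1, int(rng.exponential(2.0 if on else 1.5) * 90))
            env[i : i + dur] = 1.0 if on else 0.0
            i += dur
            on = not on
        acc += rng.normal(0, 0.03, size=(3, n))
        acc += env * rng.normal(0, profile.imu_amp, size=(3, n))
        gyr += rng.normal(0, 3.0, size=(3, n)) + env * rng.normal(
            0, 40.0, size=(3, n)
        )
    elif profile.imu_regime == "vehicle":
        acc[2] = 1.0
        # road vibration: smoothed white noise
        raw = rng.normal(0, 0.25, size=(3, n))
        kernel = np.ones(5) / 5
        vib = np.stack([np.convolve(r, kernel, mode="same") for r in raw])
        acc += vib * np.array([0.5, 0.5, 1.0])[:, None]
        gyr += rng.normal(0, 4.0, size=(3, n))
    else:  # pragma: no cover
        raise ValueError(f"unknown regime {profile.imu_regime!r}")
    acc[:3] += tilt[:, None]
    return np.vstack([acc, gyr])


def _draw_tags(
    profile: ActivityProfile,
    profiles: dict[str, ActivityProfile],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    source = profile
    if profile.confusion_partner and rng.random() < config.confusion_rate:
        source = profiles[profile.confusion_partner]
    out = []
    for _ in range(config.tag_len):
        if rng.random() < config.tag_mixture:
            out.append(str(rng.choice(source.signature_tags, p=_SIG_PROBS)))
        else:
            out.append(str(rng.choice(BACKGROUND_TAGS, p=_BG_PROBS)))
    return tuple(out)


def _draw_bout_start(
    profile: ActivityProfile, week: int, rng: np.random.Generator
) -> dt.datetime:
    """Start datetime from the activity's schedule affinity; each bout lives
    in its own calendar week so exported streams never overlap."""
    weekday = rng.random() < 5 / 7
    for _ in range(2):
        col = 2 if weekday else 3
        hour_w = np.zeros(24)
        for s, e, *vals in profile.schedule:
            hour_w[s:e] = np.maximum(hour_w[s:e], vals[col - 2])
        if hour_w.sum() > 0:
            break
        weekday = not weekday  # activity never happens on this day type
    else:
        hour_w = np.ones(24)
    hour = int(rng.choice(24, p=hour_w / hour_w.sum()))
    minute = int(rng.integers(0, 56))
    base = _WEEKDAY_BASE if weekday else _WEEKEND_BASE
    return base + dt.timedelta(weeks=week, hours=hour, minutes=minute)


def _epoch(d: dt.datetime) -> float:
    return d.replace(tzinfo=dt.timezone.utc).timestamp()


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the complete aligned bundle for one seed."""
    rng = np.random.default_rng(config.seed)
    profiles = config.profiles
    bouts: list[Bout] = []
    week = 0
    for label in config.frame.labels:
        profile = profiles[label]
        remaining = config.samples_per_class
        bout_idx = 0
        while remaining > 0:
            n_img = min(config.images_per_bout, remaining)
            remaining -= n_img
            start = _draw_bout_start(profile, week, rng)
            week += 1
            t0 = _epoch(start)
            image_times = t0 + config.image_period * np.arange(n_img)
            # IMU covers every window with margin
            tt = np.arange(
                t0 - 2.0, image_times[-1] + 2.0, 1.0 / config.imu_rate
            )
            sig = _imu_signals(profile, tt - tt[0], rng)
            imu = pd.DataFrame({"time": tt})
            for c, row in zip(CHANNELS, sig):
                imu[c] = row
            lat = config.anchor_lat + rng.normal(0, 0.01)
            lon = config.anchor_lon + rng.normal(0, 0.01)
            gps: list[GpsFix | None] = []
            for ts in image_times:
                if rng.random() < config.gps_gap_rate:
                    gps.append(None)
                    continue
                speed = float(
                    rng.lognormal(np.log(profile.speed_mean), profile.speed_sigma)
                )
                gps.append(GpsFix(float(ts), lat, lon, speed))
            ids = [f"{label}-{bout_idx:03d}-{i:03d}" for i in range(n_img)]
            stamps = [
                (start + dt.timedelta(seconds=i * config.image_period)).isoformat()
                for i in range(n_img)
            ]
            tags = [
                BagOfTags(iid, stamp, _draw_tags(profile, profiles, config, rng))
                for iid, stamp in zip(ids, stamps)
            ]
            bouts.append(
                Bout(
                    label=label, start=start, image_ids=ids,
                    image_times=image_times, tags=tags, imu=imu, gps=gps,
                )
            )
            bout_idx += 1
    bouts.sort(key=lambda b: b.image_times[0])
    return SyntheticDataset(
        config=config,
        bouts=bouts,
        weekday_table=generate_knowledge_table(config, "weekday"),
        weekend_table=generate_knowledge_table(config, "weekend"),
    )
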