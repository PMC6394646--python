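"""Entropy-weighted TF-IDF classification of image tag lists.

An external image annotator reduces every egocentric image to a "bag of
tags" (BoT): an unordered list of ~20 textual tags.  Activity recognition
then becomes text classification: for each activity class a *class center*
is learned — the M tags with the highest entropy-weighted TF-IDF — and a new
image is scored by cosine similarity between its tag-count vector and every
class center.  The normalized similarity vector is the image-source BBA.

The weight of tag i for class k is

    w(i, k) = tf(i, k) · idf(i) · e1(i, k) · R(e2(i))

where

* ``tf(i, k)`` is the frequency of tag i in class k's pooled tags,
* ``idf(i) = ln(|D| / (d(i) + 1))`` with |D| the total number of BoT
  documents and d(i) the number containing tag i (one BoT = one document),
* ``e1(i, k)`` is the Shannon entropy (base 2) of tag i's occurrence counts
  across the individual BoTs of class k — large when the tag recurs evenly
  through the class, i.e. when it is a stable part of the class's object
  combination,
* ``e2(i)`` is the entropy of tag i's document counts across the K classes —
  large when the tag appears indiscriminately in every class — remapped by
  ``R(e2) = 1 − e2 / (log2 K + λ)`` so discriminative tags score high; the
  small constant λ > 0 keeps R positive even for perfectly uniform tags.

With the "+1" idf smoothing a tag present in every document gets a negative
idf; final weights are clipped at zero, since negative mass is meaningless in
the top-M ranking and the cosine space.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from adlfuse.dsmt import BBA, make_bayesian_bba, uniform_bba
from adlfuse.frame import Frame

logger = logging.getLogger(__name__)


def normalize_tag(tag: str) -> str:
    """Canonical tag form: casefolded, whitespace-trimmed."""
    return tag.strip().casefold()


@dataclass(frozen=True)
class BagOfTags:
    """One image's tag list (duplicates permitted and counted)."""

    image_id: str
    timestamp: str
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        norm = tuple(normalize_tag(t) for t in self.tags if t.strip())
        if not norm:
            raise ValueError("empty bag of tags")
        object.__setattr__(self, "tags", norm)

    @property
    def counts(self) -> Counter:
        return Counter(self.tags)


def read_bot_stream(path: str | Path) -> list[BagOfTags]:
    """Read a JSON-lines tag stream: one object {id, timestamp, tags} per image."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(BagOfTags(str(obj["id"]), str(obj["timestamp"]), tuple(obj["tags"])))
    return out


def write_bot_stream(bots: Iterable[BagOfTags], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in bots:
            fh.write(
                json.dumps({"id": b.image_id, "timestamp": b.timestamp, "tags": list(b.tags)})
                + "\n"
            )


class TagCorpus:
    """Per-class BoT collections plus the derived count statistics.

    On construction the two count identities are asserted: per-class pooled
    occurrence counts equal the sum of per-BoT counts, and total document
    counts equal the sum of per-class document counts.
    """

    def __init__(self, by_class: Mapping[str, Sequence[BagOfTags]]):
        if not by_class:
            raise ValueError("empty corpus")
        for k, bots in by_class.items():
            if not bots:
                raise ValueError(f"class {k!r} has no BoTs")
        self.by_class = {k: list(v) for k, v in by_class.items()}
        self.classes = list(self.by_class)
        # per-class per-BoT occurrence counts C(B_j, T_i)
        self.bot_counts = {k: [b.counts for b in v] for k, v in self.by_class.items()}
        # per-class pooled occurrence counts C(B_{A_k}, T_i) and totals
        self.class_counts = {
            k: sum(self.bot_counts[k], Counter()) for k in self.classes
        }
        self.class_totals = {k: sum(c.values()) for k, c in self.class_counts.items()}
        # per-class document counts D(B_{A_k}, T_i)
        self.doc_counts = {
            k: Counter(t for b in v for t in set(b.tags))
            for k, v in self.by_class.items()
        }
        self.total_doc_counts = sum(self.doc_counts.values(), Counter())
        self.n_docs = sum(len(v) for v in self.by_class.values())
        self.vocabulary = sorted(self.total_doc_counts)
        for k in self.classes:  # count identities, by construction but asserted
            assert self.class_counts[k] == sum(self.bot_counts[k], Counter())
        assert self.total_doc_counts == sum(self.doc_counts.values(), Counter())

    @classmethod
    def from_labeled(
        cls, bots: Sequence[BagOfTags], labels: Sequence[str]
    ) -> "TagCorpus":
        if len(bots) != len(labels):
            raise ValueError("bots and labels differ in length")
        by_class: dict[str, list[BagOfTags]] = {}
        for b, l in zip(bots, labels):
            by_class.setdefault(l, []).append(b)
        return cls(by_class)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables of the tag classifier: M tags per center, remap constant λ."""

    m_tags: int = 20
    lam: float = 0.01

    def __post_init__(self) -> None:
        if self.m_tags < 1:
            raise ValueError("m_tags must be >= 1")
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")


@dataclass
class ClassCenter:
    """Top-M (tag, weight) pairs representing one activity class."""

    label: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        tags = [t for t, _ in self.entries]
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate tags in class center")
        if any(w < 0 for _, w in self.entries):
            raise ValueError("negative center weight")
        if any(
            w1 < w2 for (_, w1), (_, w2) in zip(self.entries, self.entries[1:])
        ):
            raise ValueError("center weights must be sorted descending")


# ---------------------------------------------------------------------------
# Weight factors


def term_frequency_idf(corpus: TagCorpus, tag: str, klass: str) -> float:
    """tf(i,k)·idf(i): class-pooled term frequency × smoothed inverse
    document frequency over all BoT documents (natural log).  May be
    negative for near-ubiquitous tags; clipping happens at the final
    weight, not here."""
    tf = corpus.class_counts[klass][tag] / corpus.class_totals[klass]
    if tf == 0.0:
        return 0.0
    idf = math.log(corpus.n_docs / (corpus.total_doc_counts[tag] + 1))
    return tf * idf


def inter_class_entropy(corpus: TagCorpus, tag: str, klass: str) -> float:
    """e1(i,k): entropy of the tag's occurrence counts over the class's BoTs.

    0·log2(0) is taken as 0; a tag absent from the class has e1 = 0.
    Bounded by log2 of the number of BoTs in the class.
    """
    total = corpus.class_counts[klass][tag]
    if total == 0:
        return 0.0
    e = 0.0
    for counts in corpus.bot_counts[klass]:
        c = counts[tag]
        if c:
            p = c / total
            e -= p * math.log2(p)
    return e


def intra_class_entropy(corpus: TagCorpus, tag: str) -> float:
    """e2(i): entropy of the tag's document counts across the K classes.

    Bounded by log2 K; 0 when the tag occurs in the BoTs of one class only.
    """
    total = corpus.total_doc_counts[tag]
    if total == 0:
        return 0.0
    e = 0.0
    for k in corpus.classes:
        d = corpus.doc_counts[k][tag]
        if d:
            p = d / total
            e -= p * math.log2(p)
    return e


def entropy_remap(e2: float, n_classes: int, lam: float) -> float:
    """R(e2) = 1 − e2/(log2 K + λ); in (0, 1] for 0 ≤ e2 ≤ log2 K, λ > 0."""
    return 1.0 - e2 / (math.log2(n_classes) + lam)


def entropy_tfidf_weight(
    corpus: TagCorpus, config: ClassifierConfig, tag: str, klass: str
) -> float:
    """Full per-(tag, class) weight tf·idf·e1·R(e2), clipped at 0."""
    ti = term_frequency_idf(corpus, tag, klass)
    if ti == 0.0:
        return 0.0
    e1 = inter_class_entropy(corpus, tag, klass)
    if e1 == 0.0:
        return 0.0
    r = entropy_remap(intra_class_entropy(corpus, tag), len(corpus.classes), config.lam)
    return max(0.0, ti * e1 * r)


# ---------------------------------------------------------------------------
# Classifier


def build_classifier(
    corpus: TagCorpus, config: ClassifierConfig = ClassifierConfig()
) -> dict[str, ClassCenter]:
    """Learn one class center per activity: the M highest-weight tags.

    Only strictly positive weights enter a center; ties are broken
    lexicographically by tag.  A class with fewer than M positive-weight tags
    yields a shorter center with a logged warning.
    """
    centers: dict[str, ClassCenter] = {}
    for k in corpus.classes:
        weights = []
        for tag in corpus.class_counts[k]:
            w = entropy_tfidf_weight(corpus, config, tag, k)
            if w > 0:
                weights.append((tag, w))
        weights.sort(key=lambda tw: (-tw[1], tw[0]))
        if len(weights) < config.m_tags:
            logger.warning(
                "class %r has only %d positive-weight tags (M=%d)",
                k, len(weights), config.m_tags,
            )
        centers[k] = ClassCenter(k, weights[: config.m_tags])
    return centers


def save_classifier(centers: Mapping[str, ClassCenter], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: c.entries for k, c in centers.items()}, fh, indent=1)


def load_classifier(path: str | Path) -> dict[str, ClassCenter]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: ClassCenter(k, [(t, w) for t, w in v]) for k, v in raw.items()}


def classify_bot(
    bot: BagOfTags, centers: Mapping[str, ClassCenter], frame: Frame
) -> tuple[BBA, bool]:
    """Cosine-similarity classification of one tag list into a Bayesian BBA.

    The BoT's raw tag counts and every class center's weights are embedded in
    the union vocabulary of all centers (out-of-vocabulary tags are ignored);
    per-class cosine similarities are normalized to sum 1.  If the BoT shares
    no tag with any center the image source abstains: uniform BBA with the
    low-confidence flag set.

    Returns ``(bba, low_confidence)``.
    """
    missing = [l for l in frame.labels if l not in centers]
    if missing:
        raise ValueError(f"classifier lacks centers for {missing}")
    vocab = sorted({t for c in centers.values() for t, _ in c.entries})
    vidx = {t: i for i, t in enumerate(vocab)}
    x = np.zeros(len(vocab))
    for t, c in bot.counts.items():
        if t in vidx:
            x[vidx[t]] = c
    xn = np.linalg.norm(x)
    sims = np.zeros(len(frame))
    if xn > 0:
        for j, label in enumerate(frame.labels):
            v = np.zeros(len(vocab))
            for t, w in centers[label].entries:
                v[vidx[t]] = w
            vn = np.linalg.norm(v)
            if vn > 0:
                sims[j] = float(x @ v) / (xn * vn)
    if sims.sum() <= 0:
        logger.debug("BoT %s shares no tag with any center; abstaining", bot.image_id)
        return uniform_bba(frame), True
    return make_bayesian_bba(frame, sims), False
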