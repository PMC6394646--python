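"""Two-level hierarchical fusion network with descending candidate sets.

The three sources differ in reliability: the wearer's own knowledge and the
image evidence are high-priority, the motion sensors low-priority (many
daily activities are sedentary and indistinguishable by motion alone).  The
network therefore fuses knowledge and image first (PCR5).  Only when that
pair *conflicts* are the sensors consulted: the candidate set descends to
the Nc top-belief activities of the level-1 result, all three source BBAs
are restricted and renormalized to those candidates, and a three-source
PCR6 combination decides among them.  Sensors are never consulted at level
1 — a hard contract of the architecture.

Two conflict predicates are available:

* ``"argmax"`` (default): the knowledge and image top decisions disagree
  (ties broken by frame order before comparison);
* ``"mass"``: the conjunctive conflict mass of the pair exceeds a threshold.

A simplified variant covers deployments without knowledge tables: the
candidates descend directly from the image BBA and the image and sensor
sources are fused with PCR5 over them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

import numpy as np

from adlfuse.dsmt import (
    BBA,
    FusionTrace,
    argmax_activity,
    combine_pcr5,
    combine_pcr6,
    restrict_and_renormalize,
)
from adlfuse.frame import Frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionConfig:
    """Tunables of the fusion network.

    ``nc`` is the number of candidate activities passed to the second level;
    ``conflict_rule`` selects the conflict predicate; ``force_three_source``
    bypasses the hierarchy entirely and always runs plain three-source PCR6
    over the full frame.
    """

    nc: int = 3
    conflict_rule: Literal["argmax", "mass"] = "argmax"
    conflict_threshold: float = 0.5
    force_three_source: bool = False

    def validate(self, frame: Frame) -> None:
        if not 1 <= self.nc <= len(frame):
            raise ValueError(f"nc must be in 1..{len(frame)}")


@dataclass
class FusionDecision:
    """Outcome of one fused sample.

    When no conflict occurred the second level never ran: ``candidates`` and
    ``level2`` are None and ``final`` is the arg-max of ``level1``.
    """

    final: str
    conflict: bool
    level1: BBA
    candidates: list[str] | None = None
    level2: BBA | None = None
    degenerate_restriction: bool = False
    trace: FusionTrace | None = field(default=None, repr=False)

    def to_json_dict(self) -> dict:
        def masses(b: BBA | None):
            return None if b is None else b.to_json_dict()["masses"]

        return {
            "final": self.final,
            "conflict": self.conflict,
            "candidates": self.candidates,
            "level1": masses(self.level1),
            "level2": masses(self.level2),
        }


def _top_candidates(m: BBA, nc: int) -> list[str]:
    """Nc top-belief singletons, descending; boundary ties keep the smaller
    frame index (np.argsort with stable kind on negated beliefs)."""
    beliefs = m.singleton_beliefs()
    order = np.argsort(-beliefs, kind="stable")
    return [m.frame.labels[i] for i in order[:nc]]


def _conflict(knowledge: BBA, image: BBA, config: FusionConfig) -> bool:
    if config.conflict_rule == "argmax":
        return argmax_activity(knowledge) != argmax_activity(image)
    trace = FusionTrace()
    combine_pcr5(knowledge, image, trace=trace)
    return trace.total_conflict > config.conflict_threshold


def fuse_full(
    knowledge: BBA, image: BBA, sensors: BBA, config: FusionConfig = FusionConfig()
) -> FusionDecision:
    """Full two-level fusion of knowledge, image, and sensor BBAs."""
    frame = knowledge.frame
    if image.frame != frame or sensors.frame != frame:
        raise ValueError("sources must share the same frame")
    config.validate(frame)

    if config.force_three_source:
        restricted = [
            restrict_and_renormalize(m, frame.labels)[0]
            for m in (knowledge, image, sensors)
        ]
        trace = FusionTrace()
        fused = combine_pcr6(restricted, trace=trace)
        return FusionDecision(
            final=argmax_activity(fused),
            conflict=True,
            level1=combine_pcr5(knowledge, image),
            candidates=list(frame.labels),
            level2=fused,
            trace=trace,
        )

    trace = FusionTrace()
    level1 = combine_pcr5(knowledge, image, trace=trace)
    if not _conflict(knowledge, image, config):
        return FusionDecision(
            final=argmax_activity(level1),
            conflict=False,
            level1=level1,
            trace=trace,
        )
    candidates = _top_candidates(level1, config.nc)
    degenerate = False
    restricted = []
    for m in (knowledge, image, sensors):
        r, flag = restrict_and_renormalize(m, candidates)
        degenerate = degenerate or flag
        restricted.append(r)
    trace2 = FusionTrace()
    level2 = combine_pcr6(restricted, trace=trace2)
    return FusionDecision(
        final=argmax_activity(level2),
        conflict=True,
        level1=level1,
        candidates=candidates,
        level2=level2,
        degenerate_restriction=degenerate,
        trace=trace2,
    )


def fuse_simplified(
    image: BBA, sensors: BBA, config: FusionConfig = FusionConfig()
) -> FusionDecision:
    """Knowledge-free variant: candidates descend from the image BBA."""
    frame = image.frame
    if sensors.frame != frame:
        raise ValueError("sources must share the same frame")
    config.validate(frame)
    candidates = _top_candidates(image, config.nc)
    ri, fi = restrict_and_renormalize(image, candidates)
    rs, fs = restrict_and_renormalize(sensors, candidates)
    trace = FusionTrace()
    fused = combine_pcr5(ri, rs, trace=trace)
    return FusionDecision(
        final=argmax_activity(fused),
        conflict=True,
        level1=ri,
        candidates=candidates,
        level2=fused,
        degenerate_restriction=fi or fs,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Pipeline


def run_pipeline(
    samples: Iterable[dict],
    config: FusionConfig = FusionConfig(),
) -> Iterator[tuple[dict, FusionDecision]]:
    """Fuse a stream of per-image samples.

    Each sample is a dict with keys ``image`` and ``sensors`` (BBAs) and
    optionally ``knowledge``; extra keys (``id``, ``timestamp``, ``label``)
    pass through.  Samples without a knowledge BBA take the simplified path.
    Samples missing a required source are skipped with a logged reason.
    """
    for sample in samples:
        image = sample.get("image")
        sensors = sample.get("sensors")
        if image is None or sensors is None:
            logger.warning(
                "sample %s missing image/sensor source; skipped", sample.get("id")
            )
            continue
        knowledge = sample.get("knowledge")
        if knowledge is not None:
            decision = fuse_full(knowledge, image, sensors, config)
        else:
            decision = fuse_simplified(image, sensors, config)
        yield sample, decision


def write_decisions(
    results: Iterable[tuple[dict, FusionDecision]], path
) -> None:
    """JSON-lines decision stream: one object per fused sample."""
    with open(path, "w") as fh:
        for sample, decision in results:
            obj = {
                "id": sample.get("id"),
                "timestamp": sample.get("timestamp"),
                **decision.to_json_dict(),
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")
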