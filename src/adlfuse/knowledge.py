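"""User-authored knowledge tables and their conversion to belief assignments.

A wearer expresses their daily routine as one or more association tables.
The required one is a time–activity table: rows are clock-time periods, and
each cell scores how plausible an activity is in that period on an integer
scale from 0 (impossible) to 10 (assured).  Optional location–activity and
activity-transition tables enrich the model.  Separate tables may be supplied
for weekdays and weekends/holidays.

Converting a timestamp into a belief assignment is row-wise normalization:
the score row whose period contains the clock time is divided by its sum.
When several tables apply (time + location + transition), each produces its
own BBA and they are chained pairwise with PCR5 in a fixed order.

Period convention: a printed range "a–b" is canonicalized to the half-open
interval [a, b + 1 minute), so consecutive printed rows such as "6:51–7:20"
and "7:21–7:30" partition the day without double ownership; an end time of
"00:00" means midnight at the end of the day.  Timestamps falling in an
uncovered gap follow the configured gap policy (default: nearest period).
"""

from __future__ import annotations

import datetime as dt
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from adlfuse.dsmt import BBA, combine_pcr5, make_bayesian_bba, uniform_bba
from adlfuse.frame import DEFAULT_FRAME, Frame, normalize_label

logger = logging.getLogger(__name__)

Scope = Literal["weekday", "weekend", "any"]
GapPolicy = Literal["error", "nearest-period"]

_PERIOD_RE = re.compile(
    r"^\s*(\d{1,2}):(\d{2})\s*[-–—]\s*(\d{1,2}):(\d{2})\s*$"
)

DAY_SECONDS = 24 * 3600


def _parse_period(text: str) -> tuple[int, int]:
    """Parse "HH:MM–HH:MM" into half-open [start, end) seconds-of-day.

    The printed end minute is inclusive, so one minute is added; "00:00" as
    an end time denotes midnight at the end of the day.
    """
    m = _PERIOD_RE.match(str(text))
    if not m:
        raise ValueError(f"malformed time period {text!r}")
    h1, m1, h2, m2 = (int(g) for g in m.groups())
    if not (0 <= h1 < 24 and 0 <= m1 < 60 and 0 <= h2 <= 24 and 0 <= m2 < 60):
        raise ValueError(f"time out of range in period {text!r}")
    start = h1 * 3600 + m1 * 60
    end = h2 * 3600 + m2 * 60
    if end == 0:
        end = DAY_SECONDS
    else:
        end = min(end + 60, DAY_SECONDS)
    if end <= start:
        raise ValueError(f"period {text!r} ends before it starts")
    return start, end


@dataclass
class KnowledgeTable:
    """A time–activity (or location/transition) score table.

    ``periods`` are half-open [start, end) second-of-day intervals; ``scores``
    is an integer matrix with one row per period and one column per frame
    activity, values in 0..10.
    """

    frame: Frame
    periods: list[tuple[int, int]]
    scores: np.ndarray
    scope: Scope = "any"
    kind: str = "time"
    period_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.shape != (len(self.periods), len(self.frame)):
            raise ValueError("score matrix shape does not match periods × frame")
        if self.scores.min() < 0 or self.scores.max() > 10:
            raise ValueError("scores must be integers in 0..10")
        order = np.argsort([p[0] for p in self.periods])
        self.periods = [self.periods[i] for i in order]
        self.scores = self.scores[order]
        if self.period_labels:
            self.period_labels = [self.period_labels[i] for i in order]
        for (s1, e1), (s2, _) in zip(self.periods, self.periods[1:]):
            if s2 < e1:
                raise ValueError("overlapping periods after canonicalization")

    def to_csv(self, path: str | Path | None = None) -> str | None:
        """Serialize back to the CSV interchange form."""
        rows = []
        for i, (s, e) in enumerate(self.periods):
            label = (
                self.period_labels[i]
                if self.period_labels
                else _format_period(s, e)
            )
            rows.append([label, *self.scores[i].tolist()])
        df = pd.DataFrame(rows, columns=["period", *self.frame.labels])
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            return buf.getvalue()
        df.to_csv(path, index=False)
        return None


def _format_period(start: int, end: int) -> str:
    h1, m1 = divmod(start // 60, 60)
    if end == DAY_SECONDS:
        h2, m2 = 0, 0  # printed "00:00" means midnight at day end
    else:
        h2, m2 = divmod(end // 60 - 1, 60)  # printed end minute is inclusive
    return f"{h1:02d}:{m1:02d}-{h2:02d}:{m2:02d}"


def parse_table(
    source: str | Path | io.TextIOBase,
    frame: Frame = DEFAULT_FRAME,
    scope: Scope | None = None,
    kind: str = "time",
) -> KnowledgeTable:
    """Parse a knowledge-table CSV.

    The first column ("period") holds "HH:MM–HH:MM" ranges; the remaining
    header cells must be the frame's activity codes or full names.  ``scope``
    defaults to a guess from the filename ("weekend"/"weekday") and otherwise
    to "any".
    """
    if scope is None and isinstance(source, (str, Path)):
        name = Path(source).name.casefold()
        if "weekend" in name or "holiday" in name:
            scope = "weekend"
        elif "weekday" in name:
            scope = "weekday"
    scope = scope or "any"
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        raise ValueError("empty knowledge table") from None
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise ValueError("knowledge table needs a period column and activity columns")
    cols = [normalize_label(c) for c in df.columns[1:]]
    unknown = [c for c in cols if c not in frame]
    if unknown:
        raise ValueError(f"unknown activity columns: {unknown}")
    if set(cols) != set(frame.labels):
        missing = [c for c in frame.labels if c not in cols]
        raise ValueError(f"missing activity columns: {missing}")
    raw = df.iloc[:, 1:]
    raw.columns = cols
    raw = raw[list(frame.labels)]
    values = raw.to_numpy()
    if not np.all(np.equal(np.mod(values, 1), 0)):
        raise ValueError("scores must be integers")
    if kind == "time":
        periods = [_parse_period(p) for p in df.iloc[:, 0]]
    else:
        # location/transition tables key rows by category, not clock time
        periods = [(i, i + 1) for i in range(len(df))]
    return KnowledgeTable(
        frame=frame,
        periods=periods,
        scores=values.astype(int),
        scope=scope,
        kind=kind,
        period_labels=[str(p).strip() for p in df.iloc[:, 0]],
    )


@dataclass
class KnowledgeProfile:
    """A wearer's set of knowledge tables.

    At least one time–activity table is required; optional location–activity
    and activity-transition tables may be added.  At most one table per
    (kind, scope) pair.
    """

    tables: list[KnowledgeTable]

    def __post_init__(self) -> None:
        if not any(t.kind == "time" for t in self.tables):
            raise ValueError("profile needs at least one time-activity table")
        seen = set()
        for t in self.tables:
            key = (t.kind, t.scope)
            if key in seen:
                raise ValueError(f"duplicate table for {key}")
            seen.add(key)

    def select(self, kind: str, weekend: bool) -> KnowledgeTable | None:
        """Table of the given kind whose scope matches the calendar context;
        scoped tables take precedence over 'any'."""
        want = "weekend" if weekend else "weekday"
        by_scope = {t.scope: t for t in self.tables if t.kind == kind}
        return by_scope.get(want) or by_scope.get("any")


def lookup_row(
    table: KnowledgeTable,
    timestamp: dt.time | dt.datetime,
    gap_policy: GapPolicy = "nearest-period",
) -> tuple[int, np.ndarray]:
    """Locate the score row whose period contains a clock time.

    Returns ``(row_index, score_row)``.  A boundary timestamp belongs to the
    period that starts there.  For a time in an uncovered gap the policy is
    either ``"error"`` or ``"nearest-period"`` (smallest distance to a period
    edge; ties to the earlier period).
    """
    if isinstance(timestamp, dt.datetime):
        timestamp = timestamp.time()
    sec = timestamp.hour * 3600 + timestamp.minute * 60 + timestamp.second
    for i, (s, e) in enumerate(table.periods):
        if s <= sec < e:
            return i, table.scores[i]
    if gap_policy == "error":
        raise LookupError(f"time {timestamp} not covered by any period")
    dists = [
        min(abs(sec - s), abs(sec - (e - 1)), (sec + DAY_SECONDS - (e - 1)) % DAY_SECONDS)
        for s, e in table.periods
    ]
    i = int(np.argmin(dists))
    logger.warning("time %s in a table gap; using nearest period %d", timestamp, i)
    return i, table.scores[i]


def knowledge_bba(
    profile: KnowledgeProfile,
    timestamp: dt.datetime,
    *,
    weekend: bool | None = None,
    location: str | None = None,
    previous_activity: str | None = None,
    gap_policy: GapPolicy = "nearest-period",
) -> BBA:
    """Convert a timestamp (plus optional context) into the knowledge BBA.

    The matching time–activity row is normalized by its sum.  When optional
    location/transition tables exist *and* their context keys are supplied,
    each contributes its own BBA and all are chained with PCR5 in the fixed
    order time → location → transition.  An all-zero score row makes the
    source abstain (uniform BBA with a warning) rather than veto.
    """
    if weekend is None:
        weekend = timestamp.weekday() >= 5
    frame = profile.tables[0].frame

    def row_to_bba(table: KnowledgeTable, row: np.ndarray) -> BBA:
        if row.sum() == 0:
            logger.warning("all-zero score row in %s table; source abstains", table.kind)
            return uniform_bba(frame)
        return make_bayesian_bba(frame, row)

    time_table = profile.select("time", weekend)
    if time_table is None:
        raise ValueError("no applicable time-activity table")
    _, row = lookup_row(time_table, timestamp, gap_policy)
    result = row_to_bba(time_table, row)

    for kind, key in (("location", location), ("transition", previous_activity)):
        if key is None:
            continue
        table = profile.select(kind, weekend)
        if table is None:
            continue
        # for location/transition tables the "period" axis is categorical;
        # rows are matched by label
        try:
            idx = table.period_labels.index(key)
        except ValueError:
            logger.warning("%s %r not found in %s table; skipping", kind, key, kind)
            continue
        result = combine_pcr5(result, row_to_bba(table, table.scores[idx]))
    return result
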