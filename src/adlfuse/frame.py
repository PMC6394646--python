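"""Frames of discernment for activity recognition.

A frame is the exhaustive, ordered set of mutually exclusive activity labels
over which every belief assignment in the pipeline is defined.  The default
frame holds the 15 activities of daily living used throughout the package,
identified by two-letter codes in a fixed order; the order doubles as the
deterministic tie-break rule everywhere a tie can occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical 15-activity frame: code -> human-readable name, in frame order.
ACTIVITY_NAMES: dict[str, str] = {
    "CN": "cleaning",
    "CU": "computer use",
    "ET": "eating",
    "EM": "entertainment",
    "LD": "lying down",
    "MT": "meeting",
    "RD": "reading",
    "SP": "shopping",
    "TK": "talking",
    "TU": "telephone use",
    "TP": "transportation",
    "WO": "walking outside",
    "WU": "washing up",
    "TV": "watching TV",
    "WT": "writing",
}

_NAME_TO_CODE = {v.casefold(): k for k, v in ACTIVITY_NAMES.items()}


@dataclass(frozen=True)
class Frame:
    """Ordered frame of discernment.

    Parameters
    ----------
    labels
        Unique activity identifiers.  The order is semantically meaningful:
        it defines canonical subset representation and tie-breaking.
    """

    labels: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a frame needs at least 2 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("frame labels must be unique")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"label {label!r} not in frame") from None

    def canonical(self, members) -> tuple[str, ...]:
        """Return a subset of labels in canonical (frame-order) form."""
        idx = sorted({self.index(m) for m in members})
        if not idx:
            raise ValueError("empty subset has no canonical form")
        return tuple(self.labels[i] for i in idx)


def normalize_label(label: str) -> str:
    """Map an activity code or full name to its canonical frame code.

    Accepts either the two-letter code ("TV") or the full name
    ("watching TV", case-insensitive); returns the code unchanged for
    labels outside the default activity set.
    """
    s = label.strip()
    if s in ACTIVITY_NAMES:
        return s
    return _NAME_TO_CODE.get(s.casefold(), s)


DEFAULT_FRAME = Frame(tuple(ACTIVITY_NAMES))
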