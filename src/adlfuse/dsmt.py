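"""Belief assignments and proportional-conflict-redistribution combination.

The combination rules here operate on basic belief assignments (BBAs) over a
shared frame of discernment.  Focal elements are non-empty subsets of the
frame in the power-set (Shafer) model: distinct singletons intersect to the
empty set, and the full frame Θ is admitted so that a vacuous (total
ignorance) BBA exists.  Free-model intersection elements are not enumerated;
every computation the package performs lives in this restricted model.

Two combination rules are provided:

``combine_pcr5``
    The two-source rule, implemented term by term from its closed form: a
    conjunctive consensus pass plus, for every pair of focal elements with
    empty intersection, redistribution of the conflicting product back to the
    two generating elements in proportion to their masses.

``combine_pcr6``
    The s-source generalization, implemented by enumerating ordered tuples of
    focal elements (one per source): tuples with a non-empty common
    intersection contribute their product to the consensus; totally
    conflicting tuples have their product split among the s participating
    focal elements proportionally to the mass each source assigned.  For two
    sources this coincides with PCR5.

``pcr_bruteforce`` is a deliberately slow, exact-rational reference
implementation written from the per-source permutation form of the rule; it
exists so the fast implementations can be validated against an independent
derivation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from adlfuse.frame import Frame

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-6  # constructor auto-renormalization band
_MASS_ATOL = 1e-9  # invariant tolerance on Σ masses


class DegenerateSourceError(ValueError):
    """Raised when a source carries no belief at all (all-zero weights)."""


def _as_subset(frame: Frame, key) -> frozenset[int]:
    """Coerce a focal-element key (label, iterable of labels) to index form."""
    if isinstance(key, str):
        return frozenset((frame.index(key),))
    idx = frozenset(frame.index(k) for k in key)
    if not idx:
        raise ValueError("focal element must be a non-empty subset")
    return idx


@dataclass(frozen=True)
class BBA:
    """Basic belief assignment over a frame.

    Masses are stored on canonical focal elements (frozen sets of frame
    indices); zero-mass elements are dropped.  The invariant Σ m = 1 within
    1e-9 and m(∅) = 0 is enforced at construction.
    """

    frame: Frame
    _masses: dict[frozenset[int], float] = field(repr=False)

    def __post_init__(self) -> None:
        total = sum(self._masses.values())
        if any(v < 0 for v in self._masses.values()):
            raise ValueError("negative mass")
        if abs(total - 1.0) > _MASS_ATOL:
            raise ValueError(f"masses sum to {total!r}, not 1")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_masses(
        cls,
        frame: Frame,
        masses: Mapping,
        *,
        normalize: bool = False,
    ) -> "BBA":
        """Build a BBA from a mapping of focal elements to masses.

        Keys may be single labels or iterables of labels.  If the masses sum
        to 1 within 1e-6 they are silently renormalized (a warning is logged
        for deviations above 1e-9); with ``normalize=True`` any positive sum
        is accepted and renormalized — the intended path for belief rows
        published at limited decimal precision.
        """
        acc: dict[frozenset[int], float] = {}
        for key, val in masses.items():
            v = float(val)
            if v < 0:
                raise ValueError(f"negative mass for {key!r}")
            if v == 0.0:
                continue
            sub = _as_subset(frame, key)
            acc[sub] = acc.get(sub, 0.0) + v
        total = sum(acc.values())
        if total <= 0:
            raise DegenerateSourceError("degenerate source: all masses zero")
        if not normalize and abs(total - 1.0) > _SUM_TOL:
            raise ValueError(
                f"masses sum to {total!r}; deviation exceeds {_SUM_TOL} "
                "(pass normalize=True for rounded published rows)"
            )
        if abs(total - 1.0) > _MASS_ATOL:
            if not normalize:
                logger.warning("renormalizing masses with sum %.12g", total)
            acc = {k: v / total for k, v in acc.items()}
        return cls(frame, acc)

    # -- accessors ---------------------------------------------------------

    def mass(self, key) -> float:
        """Mass of one focal element (0.0 if not focal)."""
        return self._masses.get(_as_subset(self.frame, key), 0.0)

    @property
    def focal_elements(self) -> list[tuple[str, ...]]:
        """Focal elements in canonical label form, ordered deterministically."""
        return [
            tuple(self.frame.labels[i] for i in sorted(sub))
            for sub in sorted(self._masses, key=lambda s: (len(s), sorted(s)))
        ]

    def items(self) -> list[tuple[frozenset[int], float]]:
        """(index-subset, mass) pairs, deterministic order, zero masses omitted."""
        return sorted(self._masses.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))

    @property
    def is_bayesian(self) -> bool:
        """True iff every focal element is a singleton."""
        return all(len(sub) == 1 for sub in self._masses)

    def singleton_beliefs(self) -> np.ndarray:
        """Per-label belief: the summed mass of every focal element containing
        the label.  For a Bayesian BBA this is just its mass vector."""
        out = np.zeros(len(self.frame))
        for sub, m in self._masses.items():
            for i in sub:
                out[i] += m
        return out

    def as_vector(self) -> np.ndarray:
        """Singleton masses in frame order (set-valued mass not included)."""
        out = np.zeros(len(self.frame))
        for sub, m in self._masses.items():
            if len(sub) == 1:
                out[next(iter(sub))] = m
        return out

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "frame": list(self.frame.labels),
            "masses": {
                "+".join(fe): self.mass(fe) for fe in self.focal_elements
            },
        }

    @classmethod
    def from_json_dict(cls, obj: dict) -> "BBA":
        frame = Frame(tuple(obj["frame"]))
        masses = {tuple(k.split("+")): v for k, v in obj["masses"].items()}
        return cls.from_masses(frame, masses)


def vacuous_bba(frame: Frame) -> BBA:
    """Total ignorance: all mass on the full frame Θ."""
    return BBA(frame, {frozenset(range(len(frame))): 1.0})


def uniform_bba(frame: Frame, labels: Iterable[str] | None = None) -> BBA:
    """Uniform Bayesian BBA over ``labels`` (default: the whole frame)."""
    labs = list(labels) if labels is not None else list(frame.labels)
    return BBA.from_masses(frame, {l: 1.0 / len(labs) for l in labs})


def make_bayesian_bba(frame: Frame, weights: Sequence[float]) -> BBA:
    """Normalize a non-negative weight vector into a Bayesian BBA.

    This is how integer score rows from knowledge tables, cosine-similarity
    vectors, and classifier posteriors all become belief assignments.
    """
    w = np.asarray(list(weights), dtype=float)
    if w.shape != (len(frame),):
        raise ValueError(
            f"expected {len(frame)} weights for frame, got {w.shape[0]}"
        )
    if np.any(w < 0):
        raise ValueError("negative weight")
    total = w.sum()
    if total <= 0:
        raise DegenerateSourceError("degenerate source: all weights zero")
    return BBA(
        frame,
        {frozenset((i,)): v / total for i, v in enumerate(w) if v > 0},
    )


# ---------------------------------------------------------------------------
# Fusion trace


@dataclass
class FusionTrace:
    """Audit record of one combination: conflicting products and their shares.

    Each entry is ``(tuple_of_focal_elements, product, shares)`` where
    ``shares`` maps source position -> mass returned to that source's focal
    element.  Diagnostic only; shares of each conflicting product sum to the
    product within 1e-9.
    """

    conjunctive_total: float = 0.0
    conflicts: list[tuple[tuple[tuple[str, ...], ...], float, dict[int, float]]] = field(
        default_factory=list
    )

    @property
    def total_conflict(self) -> float:
        return sum(p for _, p, _ in self.conflicts)

    def log(self) -> None:
        for elems, p, shares in self.conflicts:
            logger.debug("conflict %s product=%.6g shares=%s", elems, p, shares)


# ---------------------------------------------------------------------------
# Combination rules


def _check_shared_frame(sources: Sequence[BBA]) -> Frame:
    frame = sources[0].frame
    for m in sources[1:]:
        if m.frame != frame:
            raise ValueError("sources must share the same frame")
    return frame


def combine_pcr5(m1: BBA, m2: BBA, trace: FusionTrace | None = None) -> BBA:
    """Two-source proportional conflict redistribution (closed form).

    Conjunctive consensus on every pair of focal elements with non-empty
    intersection; for a conflicting pair (A, X) the product m1(A)·m2(X) is
    redistributed as m1(A)²m2(X)/(m1(A)+m2(X)) to A and
    m2(X)²m1(A)/(m2(X)+m1(A)) to X.  A redistribution term with zero
    denominator necessarily has zero numerator and is defined as 0.
    Symmetric in its arguments.
    """
    frame = _check_shared_frame((m1, m2))
    out: dict[frozenset[int], float] = {}
    labels = frame.labels
    for a, ma in m1.items():
        for x, mx in m2.items():
            inter = a & x
            p = ma * mx
            if inter:
                out[inter] = out.get(inter, 0.0) + p
            else:
                denom = ma + mx
                if denom > 0:
                    sa = ma * ma * mx / denom
                    sx = mx * mx * ma / denom
                else:  # 0/0 guard: numerator is 0 as well
                    sa = sx = 0.0
                out[a] = out.get(a, 0.0) + sa
                out[x] = out.get(x, 0.0) + sx
                if trace is not None:
                    elems = (
                        tuple(labels[i] for i in sorted(a)),
                        tuple(labels[i] for i in sorted(x)),
                    )
                    trace.conflicts.append((elems, p, {0: sa, 1: sx}))
    if trace is not None:
        trace.conjunctive_total = 1.0 - trace.total_conflict
    total = sum(out.values())
    return BBA(frame, {k: v / total for k, v in out.items() if v > 0})


def combine_pcr6(
    sources: Sequence[BBA], trace: FusionTrace | None = None
) -> BBA:
    """s-source proportional conflict redistribution (s ≥ 2).

    Every ordered tuple of focal elements (one per source) either contributes
    its mass product to the common intersection (consensus) or, when the
    intersection is empty, has that product split among the s elements of the
    tuple proportionally to the mass each source put on its own element.
    Invariant under permutation of the sources; identical to ``combine_pcr5``
    when s = 2.
    """
    sources = list(sources)
    if len(sources) < 2:
        raise ValueError("need at least 2 sources")
    frame = _check_shared_frame(sources)
    labels = frame.labels
    out: dict[frozenset[int], float] = {}
    per_source = [m.items() for m in sources]
    for combo in product(*per_source):
        elems = [c[0] for c in combo]
        masses = [c[1] for c in combo]
        p = float(np.prod(masses))
        inter = frozenset.intersection(*elems)
        if inter:
            out[inter] = out.get(inter, 0.0) + p
        else:
            denom = sum(masses)
            shares: dict[int, float] = {}
            for i, (e, mi) in enumerate(zip(elems, masses)):
                s = p * mi / denom
                out[e] = out.get(e, 0.0) + s
                shares[i] = shares.get(i, 0.0) + s
            if trace is not None:
                trace.conflicts.append(
                    (
                        tuple(tuple(labels[i] for i in sorted(e)) for e in elems),
                        p,
                        shares,
                    )
                )
    if trace is not None:
        trace.conjunctive_total = 1.0 - trace.total_conflict
    total = sum(out.values())
    return BBA(frame, {k: v / total for k, v in out.items() if v > 0})


def pcr_bruteforce(sources: Sequence[BBA]) -> dict[tuple[str, ...], Fraction]:
    """Exact-rational reference combination, from the per-source form.

    For each source i and focal element A with m_i(A) > 0, enumerate every
    ordered tuple of the *other* sources' focal elements whose joint
    intersection with A is empty, and credit A with
    m_i(A)² · Π_j m_j(Y_j) / (m_i(A) + Σ_j m_j(Y_j)); add the conjunctive
    consensus over all totally ordered tuples.  Computed in ``Fraction``
    arithmetic so it can serve as an exact oracle for the float
    implementations.  Masses are rationalized via ``Fraction(float)`` (exact
    binary representation), so no rounding enters the reference path.
    """
    sources = list(sources)
    if len(sources) < 2:
        raise ValueError("need at least 2 sources")
    frame = _check_shared_frame(sources)
    labels = frame.labels
    items = [
        [(sub, Fraction(m)) for sub, m in src.items()] for src in sources
    ]
    out: dict[frozenset[int], Fraction] = {}
    # conjunctive consensus
    for combo in product(*items):
        inter = frozenset.intersection(*(c[0] for c in combo))
        if inter:
            p = Fraction(1)
            for _, m in combo:
                p *= m
            out[inter] = out.get(inter, Fraction(0)) + p
    # per-source redistribution
    for i, own in enumerate(items):
        others = [it for j, it in enumerate(items) if j != i]
        for a, ma in own:
            for combo in product(*others):
                joint = a
                for e, _ in combo:
                    joint = joint & e
                if joint:
                    continue
                prod_y = Fraction(1)
                sum_y = Fraction(0)
                for _, my in combo:
                    prod_y *= my
                    sum_y += my
                out[a] = out.get(a, Fraction(0)) + ma * ma * prod_y / (ma + sum_y)
    total = sum(out.values())
    return {
        tuple(labels[i] for i in sorted(sub)): v / total for sub, v in out.items()
    }


# ---------------------------------------------------------------------------
# Candidate-set utilities


def restrict_and_renormalize(
    m: BBA, candidates: Iterable[str]
) -> tuple[BBA, bool]:
    """Restrict a BBA to a candidate label set and renormalize.

    Focal elements are intersected with the candidate set; elements whose
    intersection is empty are dropped and the surviving masses are
    renormalized to 1.  If the restriction drops all mass the uniform BBA
    over the candidates is returned with the degenerate flag set — the
    source abstains on the candidate set rather than vetoing it.

    Returns ``(restricted_bba, degenerate_flag)``.
    """
    cand = list(dict.fromkeys(candidates))
    if not cand:
        raise ValueError("empty candidate set")
    cidx = frozenset(m.frame.index(c) for c in cand)
    out: dict[frozenset[int], float] = {}
    for sub, mass in m.items():
        inter = sub & cidx
        if inter:
            out[inter] = out.get(inter, 0.0) + mass
    total = sum(out.values())
    if total <= 0:
        warnings.warn(
            "restriction dropped all mass; falling back to uniform over candidates",
            stacklevel=2,
        )
        return uniform_bba(m.frame, cand), True
    return BBA(m.frame, {k: v / total for k, v in out.items()}), False


def argmax_activity(m: BBA) -> str:
    """Label with the highest belief; ties go to the earlier frame label.

    Non-Bayesian BBAs are first reduced to per-label beliefs by summing the
    mass of every focal element containing the label (so mass on Θ counts
    toward every label equally and cannot break a tie in either direction).
    """
    beliefs = m.singleton_beliefs()
    return m.frame.labels[int(np.argmax(beliefs))]
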