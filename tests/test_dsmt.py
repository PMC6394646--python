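"""Belief-assignment invariants and the PCR combination rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlfuse.dsmt import (
    BBA,
    DegenerateSourceError,
    FusionTrace,
    argmax_activity,
    combine_pcr5,
    combine_pcr6,
    make_bayesian_bba,
    pcr_bruteforce,
    restrict_and_renormalize,
    uniform_bba,
    vacuous_bba,
)
from adlfuse.frame import DEFAULT_FRAME, Frame

F2 = Frame(("a", "b"))
F4 = Frame(("a", "b", "c", "d"))


def bayesian(frame, *weights):
    return make_bayesian_bba(frame, weights)


@st.composite
def random_bba(draw, frame, allow_theta=True):
    n = len(frame)
    weights = draw(
        st.lists(st.floats(0.0, 1.0), min_size=n, max_size=n).filter(
            lambda w: sum(w) > 1e-6
        )
    )
    theta = draw(st.floats(0.0, 1.0)) if allow_theta else 0.0
    total = sum(weights) + theta
    masses = {l: w / total for l, w in zip(frame.labels, weights) if w > 0}
    if theta > 0:
        masses[frame.labels] = theta / total
    return BBA.from_masses(frame, masses)


class TestMakeBayesian:
    def test_uniform_weights(self):
        bba = make_bayesian_bba(DEFAULT_FRAME, [1.0] * 15)
        assert np.allclose(bba.as_vector(), 1 / 15)

    def test_two_cell_normalization(self):
        bba = bayesian(F2, 9, 2)
        assert bba.mass("a") == pytest.approx(9 / 11)
        assert bba.mass("b") == pytest.approx(2 / 11)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateSourceError):
            make_bayesian_bba(F2, [0, 0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            make_bayesian_bba(F2, [1, -1])

    def test_scale_invariance(self):
        a = make_bayesian_bba(F4, [2, 10, 1, 3])
        b = make_bayesian_bba(F4, [6, 30, 3, 9])
        assert np.allclose(a.as_vector(), b.as_vector())


class TestBBAInvariants:
    def test_rounded_rows_need_explicit_normalize(self):
        rounded = {"a": 0.5001, "b": 0.5002}
        with pytest.raises(ValueError):
            BBA.from_masses(F2, rounded)
        bba = BBA.from_masses(F2, rounded, normalize=True)
        assert bba.mass("a") + bba.mass("b") == pytest.approx(1.0, abs=1e-12)

    def test_bayesian_predicate(self):
        assert bayesian(F2, 1, 1).is_bayesian
        assert not vacuous_bba(F2).is_bayesian

    def test_json_round_trip(self):
        bba = BBA.from_masses(F4, {"a": 0.3, ("b", "c"): 0.2, F4.labels: 0.5})
        back = BBA.from_json_dict(bba.to_json_dict())
        assert back.frame == bba.frame
        for fe in bba.focal_elements:
            assert back.mass(fe) == pytest.approx(bba.mass(fe), abs=1e-15)


class TestPCR5:
    def test_two_label_worked_case(self):
        # conflicting products 0.7*0.8=0.56 and 0.3*0.2=0.06 redistribute
        # proportionally: hand enumeration gives (0.4253..., 0.5746...)
        r = combine_pcr5(bayesian(F2, 0.7, 0.3), bayesian(F2, 0.2, 0.8))
        assert r.mass("a") == pytest.approx(0.4253, abs=5e-5)
        assert r.mass("b") == pytest.approx(0.5747, abs=5e-5)

    def test_vacuous_is_neutral(self):
        m1 = bayesian(F4, 0.4, 0.3, 0.2, 0.1)
        r = combine_pcr5(m1, vacuous_bba(F4))
        assert np.allclose(r.as_vector(), m1.as_vector())

    def test_certainty_is_idempotent(self):
        m = bayesian(F2, 1, 0)
        r = combine_pcr5(m, m)
        assert r.mass("a") == pytest.approx(1.0)

    def test_mismatched_frames_rejected(self):
        with pytest.raises(ValueError):
            combine_pcr5(bayesian(F2, 1, 1), bayesian(F4, 1, 1, 1, 1))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(random_bba(F4), random_bba(F4))
    def test_symmetry_and_mass_conservation(self, m1, m2):
        r12 = combine_pcr5(m1, m2)
        r21 = combine_pcr5(m2, m1)
        total = sum(m for _, m in r12.items())
        assert total == pytest.approx(1.0, abs=1e-9)
        for fe in r12.focal_elements:
            assert r12.mass(fe) == pytest.approx(r21.mass(fe), abs=1e-12)

    def test_trace_conflict_accounting(self):
        m1 = bayesian(F2, 0.7, 0.3)
        m2 = bayesian(F2, 0.2, 0.8)
        trace = FusionTrace()
        combine_pcr5(m1, m2, trace=trace)
        # conjunctive consensus = 0.7*0.2 + 0.3*0.8 = 0.38
        assert trace.total_conflict == pytest.approx(1 - 0.38, abs=1e-12)
        for _, product, shares in trace.conflicts:
            assert sum(shares.values()) == pytest.approx(product, abs=1e-9)


class TestPCR6:
    def test_matches_pcr5_for_two_sources(self, rng):
        for _ in range(50):
            size = int(rng.integers(2, 16))
            frame = Frame(tuple(f"L{i}" for i in range(size)))
            m1 = make_bayesian_bba(frame, rng.dirichlet(np.ones(size)))
            m2 = make_bayesian_bba(frame, rng.dirichlet(np.ones(size)))
            a = combine_pcr5(m1, m2).as_vector()
            b = combine_pcr6([m1, m2]).as_vector()
            assert np.abs(a - b).max() < 1e-12

    def test_three_identical_certainties(self):
        m = bayesian(F4, 0, 1, 0, 0)
        r = combine_pcr6([m, m, m])
        assert r.mass("b") == pytest.approx(1.0)

    def test_fewer_than_two_sources_rejected(self):
        with pytest.raises(ValueError):
            combine_pcr6([bayesian(F2, 1, 1)])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(random_bba(F4), random_bba(F4), random_bba(F4))
    def test_permutation_invariance(self, m1, m2, m3):
        base = combine_pcr6([m1, m2, m3]).singleton_beliefs()
        for order in ((m2, m3, m1), (m3, m1, m2), (m2, m1, m3)):
            assert np.allclose(
                combine_pcr6(list(order)).singleton_beliefs(), base, atol=1e-12
            )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        random_bba(Frame(("a", "b", "c", "d")), allow_theta=False),
        random_bba(Frame(("a", "b", "c", "d")), allow_theta=False),
        random_bba(Frame(("a", "b", "c", "d")), allow_theta=False),
    )
    def test_matches_exact_oracle(self, m1, m2, m3):
        got = combine_pcr6([m1, m2, m3])
        ref = pcr_bruteforce([m1, m2, m3])
        for lab in m1.frame.labels:
            assert got.mass(lab) == pytest.approx(
                float(ref.get((lab,), 0.0)), abs=1e-10
            )


class TestRestrictAndArgmax:
    def test_proportional_renormalization(self):
        m = bayesian(Frame(("a", "b", "c")), 0.5, 0.3, 0.2)
        r, flag = restrict_and_renormalize(m, ["a", "b"])
        assert not flag
        assert r.mass("a") == pytest.approx(0.625)
        assert r.mass("b") == pytest.approx(0.375)

    def test_full_frame_is_identity(self):
        m = bayesian(F4, 0.4, 0.3, 0.2, 0.1)
        r, flag = restrict_and_renormalize(m, F4.labels)
        assert not flag
        assert np.allclose(r.as_vector(), m.as_vector())

    def test_total_loss_falls_back_to_uniform(self):
        m = bayesian(Frame(("a", "b", "c")), 0, 0, 1)
        with pytest.warns(UserWarning):
            r, flag = restrict_and_renormalize(m, ["a", "b"])
        assert flag
        assert r.mass("a") == pytest.approx(0.5)

    def test_set_valued_mass_survives_restriction(self):
        m = BBA.from_masses(F4, {"a": 0.4, ("b", "c"): 0.6})
        r, _ = restrict_and_renormalize(m, ["a", "b"])
        assert r.mass("a") == pytest.approx(0.4)
        assert r.mass("b") == pytest.approx(0.6)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            restrict_and_renormalize(bayesian(F2, 1, 1), [])

    def test_argmax_and_tie_break(self):
        assert argmax_activity(bayesian(Frame(("x", "y", "z")), 0.1, 0.8, 0.1)) == "y"
        assert argmax_activity(uniform_bba(F4)) == "a"  # earliest label wins

    def test_argmax_reduces_set_valued_mass(self):
        m = BBA.from_masses(F4, {"a": 0.3, ("b", "c"): 0.5, F4.labels: 0.2})
        # beliefs: a=0.5, b=0.7, c=0.7, d=0.2 -> b by frame-order tie-break
        assert argmax_activity(m) == "b"
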