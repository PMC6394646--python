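"""Entropy-weighted TF-IDF factors, class centers, and cosine classification."""

import math

import numpy as np
import pytest

from adlfuse.bot import (
    BagOfTags,
    ClassCenter,
    ClassifierConfig,
    TagCorpus,
    build_classifier,
    classify_bot,
    entropy_remap,
    entropy_tfidf_weight,
    inter_class_entropy,
    intra_class_entropy,
    term_frequency_idf,
)
from adlfuse.frame import Frame


def bot(iid, *tags):
    return BagOfTags(iid, "2024-01-01T12:00:00", tuple(tags))


@pytest.fixture
def two_class_corpus():
    """2 classes × 2 BoTs; small enough for hand evaluation of every factor."""
    return TagCorpus(
        {
            "work": [bot("w1", "keyboard", "desk", "screen", "lamp"),
                     bot("w2", "keyboard", "screen", "screen", "mug")],
            "meal": [bot("m1", "food", "plate", "fork", "lamp"),
                     bot("m2", "food", "meal", "plate", "mug")],
        }
    )


class TestCounts:
    def test_tags_are_normalized(self):
        b = BagOfTags("x", "t", ("  Keyboard ", "SCREEN", "screen"))
        assert b.tags == ("keyboard", "screen", "screen")
        assert b.counts["screen"] == 2

    def test_empty_bot_rejected(self):
        with pytest.raises(ValueError):
            BagOfTags("x", "t", ("  ",))

    def test_document_counts(self, two_class_corpus):
        c = two_class_corpus
        assert c.n_docs == 4
        assert c.doc_counts["work"]["keyboard"] == 2
        assert c.total_doc_counts["lamp"] == 2
        assert c.class_counts["work"]["screen"] == 3  # duplicates counted


class TestWeightFactors:
    def test_tf_absent_tag_is_zero(self, two_class_corpus):
        assert term_frequency_idf(two_class_corpus, "food", "work") == 0.0

    def test_ubiquitous_tag_weight_clipped_to_zero(self):
        # tag in all 4 documents: idf = ln(4/5) < 0 -> final weight clipped
        corpus = TagCorpus(
            {
                "a": [bot("a1", "common", "x"), bot("a2", "common", "x")],
                "b": [bot("b1", "common", "y"), bot("b2", "common", "y")],
            }
        )
        assert term_frequency_idf(corpus, "common", "a") < 0
        w = entropy_tfidf_weight(corpus, ClassifierConfig(), "common", "a")
        assert w == 0.0

    def test_single_bot_pure_tag_tf_is_one(self):
        corpus = TagCorpus({"only": [bot("o1", *["tag"] * 20)]})
        tf_idf = term_frequency_idf(corpus, "tag", "only")
        assert tf_idf == pytest.approx(1.0 * math.log(1 / 2))

    def test_e1_uniform_attains_log2_class_size(self, two_class_corpus):
        # "keyboard" occurs once in each of work's 2 BoTs -> e1 = log2 2 = 1
        assert inter_class_entropy(two_class_corpus, "keyboard", "work") == 1.0

    def test_e1_single_bot_is_zero(self, two_class_corpus):
        assert inter_class_entropy(two_class_corpus, "desk", "work") == 0.0

    def test_e1_hand_value(self):
        # per-BoT counts (2,1,1): -(1/2 log2 1/2 + 2 * 1/4 log2 1/4) = 1.5
        corpus = TagCorpus(
            {"k": [bot("1", "t", "t"), bot("2", "t"), bot("3", "t")]}
        )
        assert inter_class_entropy(corpus, "t", "k") == pytest.approx(1.5)

    def test_e2_single_class_tag_is_zero(self, two_class_corpus):
        assert intra_class_entropy(two_class_corpus, "keyboard") == 0.0

    def test_e2_uniform_attains_log2_k(self, two_class_corpus):
        # "lamp" and "mug" each appear in 1 document of each class
        assert intra_class_entropy(two_class_corpus, "lamp") == 1.0

    def test_e2_hand_value(self):
        # document counts (3,1): -(0.75 log2 0.75 + 0.25 log2 0.25) = 0.8113
        corpus = TagCorpus(
            {
                "a": [bot("a1", "t"), bot("a2", "t"), bot("a3", "t")],
                "b": [bot("b1", "t", "z")],
            }
        )
        assert intra_class_entropy(corpus, "t") == pytest.approx(0.8113, abs=1e-4)

    def test_remap_range(self):
        for k in range(2, 16):
            for e2 in np.linspace(0.0, math.log2(k), 50):
                r = entropy_remap(e2, k, 0.01)
                assert 0.0 < r <= 1.0

    def test_weight_equals_product_of_factors(self, two_class_corpus):
        cfg = ClassifierConfig()
        tag, klass = "screen", "work"
        expected = (
            term_frequency_idf(two_class_corpus, tag, klass)
            * inter_class_entropy(two_class_corpus, tag, klass)
            * entropy_remap(intra_class_entropy(two_class_corpus, tag), 2, cfg.lam)
        )
        got = entropy_tfidf_weight(two_class_corpus, cfg, tag, klass)
        assert got == pytest.approx(max(0.0, expected), abs=1e-15)


class TestClassifier:
    def test_disjoint_vocabularies_stay_separate(self):
        corpus = TagCorpus(
            {
                "a": [bot("a1", "p", "q"), bot("a2", "p", "q")],
                "b": [bot("b1", "r", "s"), bot("b2", "r", "s")],
            }
        )
        centers = build_classifier(corpus, ClassifierConfig(m_tags=5))
        assert {t for t, _ in centers["a"].entries} <= {"p", "q"}
        assert {t for t, _ in centers["b"].entries} <= {"r", "s"}

    def test_single_class_corpus_finite_weights(self):
        corpus = TagCorpus(
            {"only": [bot("o1", "a", "b"), bot("o2", "a", "c")]}
        )
        centers = build_classifier(corpus, ClassifierConfig(m_tags=3))
        assert all(np.isfinite(w) for _, w in centers["only"].entries)

    def test_centers_sorted_descending_and_capped(self, two_class_corpus):
        centers = build_classifier(two_class_corpus, ClassifierConfig(m_tags=2))
        for c in centers.values():
            assert len(c.entries) <= 2
            weights = [w for _, w in c.entries]
            assert weights == sorted(weights, reverse=True)


class TestClassifyBot:
    F2 = Frame(("a", "b"))

    def centers(self):
        return {
            "a": ClassCenter("a", [("p", 1.0)]),
            "b": ClassCenter("b", [("q", 1.0)]),
        }

    def test_pure_center_tag(self):
        bba, flag = classify_bot(bot("x", "p", "p"), self.centers(), self.F2)
        assert not flag
        assert bba.mass("a") == pytest.approx(1.0)

    def test_no_overlap_abstains(self):
        bba, flag = classify_bot(bot("x", "zzz"), self.centers(), self.F2)
        assert flag
        assert bba.mass("a") == pytest.approx(0.5)

    def test_cosine_matches_hand_computation(self):
        frame = Frame(("a", "b", "c"))
        centers = {
            "a": ClassCenter("a", [("p", 2.0), ("q", 1.0)]),
            "b": ClassCenter("b", [("q", 3.0), ("r", 1.0)]),
            "c": ClassCenter("c", [("s", 1.0)]),
        }
        # BoT counts over union vocab (p,q,r,s): (2, 1, 1, 0) plus an OOV tag
        b = bot("x", "p", "p", "q", "r", "zzz")
        x = np.array([2.0, 1.0, 1.0, 0.0])
        va = np.array([2.0, 1.0, 0.0, 0.0])
        vb = np.array([0.0, 3.0, 1.0, 0.0])
        sims = [
            x @ va / (np.linalg.norm(x) * np.linalg.norm(va)),
            x @ vb / (np.linalg.norm(x) * np.linalg.norm(vb)),
            0.0,
        ]
        expected = np.array(sims) / np.sum(sims)
        bba, flag = classify_bot(b, centers, frame)
        assert not flag
        assert np.allclose(bba.as_vector(), expected, atol=1e-12)

    def test_tag_order_is_irrelevant(self):
        c = self.centers()
        b1 = bot("x", "p", "q", "p")
        b2 = bot("x", "q", "p", "p")
        v1, _ = classify_bot(b1, c, self.F2)
        v2, _ = classify_bot(b2, c, self.F2)
        assert np.allclose(v1.as_vector(), v2.as_vector())

    def test_missing_center_rejected(self):
        with pytest.raises(ValueError):
            classify_bot(bot("x", "p"), {"a": ClassCenter("a", [("p", 1.0)])}, self.F2)
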