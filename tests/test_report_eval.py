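"""Metric correctness: gestalt matching, fuzzy windows, Jaccard, cosine,
and the random-report baselines."""

import numpy as np
import pytest

from pathreport.report import Report
from pathreport.report_eval import (
    CountEmbedder,
    VocabularyExtractor,
    baseline_scores,
    embedding_similarity,
    extract_keywords,
    fuzzy_find,
    gestalt_ratio,
    keyword_jaccard,
)

MUNICH_EXCERPT = (
    "Final diagnosis: Scar. Microscopic findings: A wedge-shaped excidate with "
    "compact massive orthohyperkeratosis, focally regular acanthosis of the "
    "epidermis with hypergranulose. Critical findings: Hypertrophic, keloid-like "
    "scar. Partial excision."
)


def recursive_block_ratio(a, b):
    """Independent oracle: recursive longest-matching-block definition.

    The longest block is found by brute force; ties resolve to the
    smallest start in `a`, then in `b` (the classic algorithm's rule).
    """

    def longest_match(a, b):
        best = (0, 0, 0)
        for i in range(len(a)):
            for j in range(len(b)):
                k = 0
                while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                    k += 1
                if k > best[2]:
                    best = (i, j, k)
        return best

    def matched_chars(a, b):
        if not a or not b:
            return 0
        i, j, k = longest_match(a, b)
        if k == 0:
            return 0
        return k + matched_chars(a[:i], b[:j]) + matched_chars(a[i + k :], b[j + k :])

    if not a and not b:
        return 1.0
    return 2.0 * matched_chars(a, b) / (len(a) + len(b))


class TestGestaltRatio:
    def test_identical_strings(self):
        assert gestalt_ratio("melanoma", "melanoma") == 1.0

    def test_known_values(self):
        assert gestalt_ratio("abcd", "bcde") == pytest.approx(0.75)
        assert gestalt_ratio("nevus", "naevus") == pytest.approx(10 / 11)

    def test_both_empty_defined_as_one(self):
        assert gestalt_ratio("", "") == 1.0

    def test_matches_recursive_oracle_on_200_random_pairs(self):
        rng = np.random.default_rng(0)
        alphabet = "abcde"
        for _ in range(200):
            a = "".join(rng.choice(list(alphabet), size=int(rng.integers(0, 12))))
            b = "".join(rng.choice(list(alphabet), size=int(rng.integers(0, 12))))
            assert gestalt_ratio(a, b) == pytest.approx(recursive_block_ratio(a, b), abs=1e-12)


class TestFuzzyFind:
    def test_exact_occurrence(self):
        assert fuzzy_find("acanthosis", MUNICH_EXCERPT)

    def test_spelling_variant_above_cutoff(self):
        assert fuzzy_find("naevus", "a compound nevus is seen")

    def test_unrelated_term_rejected(self):
        assert not fuzzy_find("xyz", "completely different words")

    def test_multi_word_window_alignment(self):
        assert fuzzy_find("basal cell carcinoma", "shows basal cell carcinomas here")

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_find("a", "a", cutoff=0.0)


class TestKeywordExtraction:
    def test_munich_terms_found(self):
        extractor = VocabularyExtractor(["scar", "acanthosis"])
        assert extract_keywords(MUNICH_EXCERPT, extractor) == {"scar", "acanthosis"}

    def test_no_vocabulary_terms(self):
        extractor = VocabularyExtractor(["melanoma"])
        assert extract_keywords("nothing relevant here", extractor) == set()

    def test_overlapping_terms_both_reported(self):
        extractor = VocabularyExtractor(["carcinoma", "basal cell carcinoma"])
        found = extract_keywords("invasive basal cell carcinoma", extractor)
        assert found == {"carcinoma", "basal cell carcinoma"}

    def test_empty_text_empty_set(self):
        assert extract_keywords("", VocabularyExtractor(["scar"])) == set()

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            VocabularyExtractor([])


class TestKeywordJaccard:
    EXTRACTOR = VocabularyExtractor(["alpha", "beta", "gamma"])

    def test_identical_reports_score_one(self):
        text = "contains alpha and beta"
        assert keyword_jaccard(text, text, self.EXTRACTOR).jaccard == 1.0

    def test_half_overlap_scores_half(self):
        res = keyword_jaccard("has alpha and beta", "has alpha only", self.EXTRACTOR)
        assert res.jaccard == 0.5
        assert res.matched == {"alpha"}

    def test_disjoint_content_scores_zero(self):
        assert keyword_jaccard("has alpha", "nothing here", self.EXTRACTOR).jaccard == 0.0

    def test_degenerate_empty_sets_flagged(self):
        res = keyword_jaccard("plain text", "plain text", self.EXTRACTOR)
        assert res.degenerate and res.jaccard == 1.0
        res = keyword_jaccard("plain text", "other text", self.EXTRACTOR)
        assert res.degenerate and res.jaccard == 0.0

    def test_reference_only_mode_is_recall(self):
        res = keyword_jaccard(
            "has alpha", "has alpha beta gamma", self.EXTRACTOR, union_mode="reference_only"
        )
        assert res.jaccard == 1.0

    def test_monotone_under_keyword_deletion(self):
        ref = "alpha beta gamma all present"
        scores = [
            keyword_jaccard(ref, gen, self.EXTRACTOR).jaccard
            for gen in ["alpha beta gamma", "alpha beta", "alpha", "none left"]
        ]
        assert scores == sorted(scores, reverse=True)


class TestEmbeddingSimilarity:
    def test_identical_texts_cosine_one(self):
        emb = CountEmbedder.from_texts(["scar tissue here"])
        assert embedding_similarity("scar tissue here", "scar tissue here", emb).cosine == pytest.approx(1.0)

    def test_orthogonal_vocabularies_cosine_zero(self):
        emb = CountEmbedder(["scar", "melanoma"])
        assert embedding_similarity("scar scar", "melanoma", emb).cosine == 0.0

    def test_matches_hand_computed_cosine(self):
        emb = CountEmbedder(["a", "b", "c"])
        # "a a b" -> (2,1,0); "a b b c" -> (1,2,1)
        expected = (2 * 1 + 1 * 2) / (np.sqrt(5) * np.sqrt(6))
        assert embedding_similarity("a a b", "a b b c", emb).cosine == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        emb = CountEmbedder(["scar"])
        with pytest.raises(ValueError):
            embedding_similarity("nothing", "scar", emb)


class TestBaselines:
    def _metric(self, extractor):
        def metric(a, b):
            return keyword_jaccard(a, b, extractor).jaccard

        return metric

    def test_identical_reports_give_unit_baselines(self):
        extractor = VocabularyExtractor(["scar"])
        corpus = [("the scar text", "x"), ("the scar text", "y"), ("the scar text", "x")]
        for mode in ("lower", "upper"):
            res = baseline_scores(corpus, mode, self._metric(extractor), rng_seed=0, n_pairs=20)
            assert res["mean"] == 1.0

    def test_upper_exceeds_lower_on_marked_corpus(self, corpus60):
        extractor = VocabularyExtractor(corpus60.vocabulary)
        corpus = [(p.report, p.label) for p in corpus60.patients]
        lower = baseline_scores(corpus, "lower", self._metric(extractor), rng_seed=1, n_pairs=60)
        upper = baseline_scores(corpus, "upper", self._metric(extractor), rng_seed=1, n_pairs=60)
        assert upper["mean"] > lower["mean"]

    def test_fixed_seed_reproduces_pairings(self):
        extractor = VocabularyExtractor(["scar"])
        corpus = [(f"report {i} scar", str(i % 2)) for i in range(10)]
        a = baseline_scores(corpus, "lower", self._metric(extractor), rng_seed=3)
        b = baseline_scores(corpus, "lower", self._metric(extractor), rng_seed=3)
        assert a["pairs"] == b["pairs"]

    def test_upper_without_shared_labels_rejected(self):
        extractor = VocabularyExtractor(["scar"])
        corpus = [("a scar", "x"), ("b scar", "y")]
        with pytest.raises(ValueError):
            baseline_scores(corpus, "upper", self._metric(extractor))
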