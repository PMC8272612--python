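"""C-Value, TF-IDF, harmonic mean, ranking and rank composition."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioterm.measures import (
    C_VALUE,
    F_TFIDF_C_M,
    TFIDF,
    c_value,
    compose_partition_ranks,
    compute_nesting,
    f_tfidf_c_m,
    rank_terms,
    score_candidates,
    tf_idf,
)

from conftest import direct_c_value, make_candidate, random_candidate_table


class TestNesting:
    def test_unigram_nested_in_bigram(self):
        cands = [
            make_candidate(("virus",), {"d1": 5}),
            make_candidate(("influenza", "virus"), {"d1": 2}),
        ]
        nesting = compute_nesting(cands)
        assert nesting["virus"] == {"influenza virus"}
        assert nesting["influenza virus"] == set()

    def test_single_candidate_has_empty_set(self):
        cands = [make_candidate(("virus",), {"d1": 5})]
        assert compute_nesting(cands) == {"virus": set()}

    def test_shared_bigram_in_two_trigrams(self):
        cands = [
            make_candidate(("b", "c"), {"d1": 6}),
            make_candidate(("a", "b", "c"), {"d1": 2}),
            make_candidate(("b", "c", "d"), {"d1": 1}),
        ]
        nesting = compute_nesting(cands)
        assert nesting["b c"] == {"a b c", "b c d"}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_substring_scan(self, seed):
        rng = random.Random(seed)
        cands = random_candidate_table(rng, n_max=40)
        nesting = compute_nesting(cands)
        lemma_sets = {c.lemmas: c.lemma_key for c in cands}
        for a in cands:
            expected = {
                lemma_sets[b.lemmas]
                for b in cands
                if len(b.lemmas) > len(a.lemmas)
                and any(
                    b.lemmas[i : i + a.length] == a.lemmas
                    for i in range(len(b.lemmas) - a.length + 1)
                )
            }
            assert nesting[a.lemma_key] == expected


class TestCValue:
    def test_unigram_without_containers(self):
        cand = make_candidate(("virus",), {"d1": 5})
        assert c_value(cand, {}, {"virus": 5}) == pytest.approx(5.0)

    def test_nested_correction_worked_value(self):
        # f("b c")=6 with one container of f=2: log2(3) * (6 - 2)
        cands = [
            make_candidate(("b", "c"), {"d1": 6}),
            make_candidate(("a", "b", "c"), {"d1": 2}),
        ]
        nesting = compute_nesting(cands)
        freqs = {"b c": 6, "a b c": 2}
        assert c_value(cands[0], nesting, freqs) == pytest.approx(math.log2(3) * 4, abs=1e-9)
        assert c_value(cands[0], nesting, freqs) == pytest.approx(6.3399, abs=1e-4)

    def test_trigram_without_containers(self):
        cand = make_candidate(("a", "b", "c"), {"d1": 2})
        assert c_value(cand, {}, {"a b c": 2}) == pytest.approx(4.0)

    def test_negative_score_clamped(self):
        cands = [
            make_candidate(("b", "c"), {"d1": 1}),
            make_candidate(("a", "b", "c"), {"d1": 9}),
        ]
        nesting = compute_nesting(cands)
        freqs = {"b c": 1, "a b c": 9}
        assert c_value(cands[0], nesting, freqs) == 0.0
        assert c_value(cands[0], nesting, freqs, clamp=False) < 0.0

    def test_unknown_candidate_rejected(self):
        with pytest.raises(KeyError):
            c_value(make_candidate(("x",), {"d1": 1}), {}, {})

    def test_monotone_in_frequency(self):
        prev = -1.0
        for f in range(1, 10):
            score = c_value(make_candidate(("a", "b"), {"d1": f}), {}, {"a b": f})
            assert score > prev
            prev = score


class TestTfIdf:
    def test_ubiquitous_term_scores_zero(self):
        cand = make_candidate(("virus",), {"d1": 3, "d2": 1, "d3": 2})
        assert tf_idf(cand, n_docs=3) == 0.0

    def test_single_document_closed_form(self):
        cand = make_candidate(("virus",), {"d1": 3})
        assert tf_idf(cand, n_docs=4) == pytest.approx(3 * math.log2(4))

    def test_mean_aggregation_closed_form(self):
        cand = make_candidate(("virus",), {"d1": 6, "d2": 2})
        assert tf_idf(cand, n_docs=4) == pytest.approx(4.0)  # mean(6*1, 2*1)
        assert tf_idf(cand, n_docs=4, agg="max") == pytest.approx(6.0)

    def test_fewer_docs_than_doc_freq_rejected(self):
        cand = make_candidate(("virus",), {"d1": 1, "d2": 1})
        with pytest.raises(ValueError):
            tf_idf(cand, n_docs=1)

    def test_monotone_in_tf_at_fixed_df(self):
        prev = -1.0
        for tf in range(1, 8):
            score = tf_idf(make_candidate(("a",), {"d1": tf}), n_docs=5)
            assert score > prev
            prev = score


class TestHarmonicMean:
    def test_equal_inputs(self):
        assert f_tfidf_c_m(4.0, 4.0) == pytest.approx(4.0)

    def test_zero_annihilates(self):
        assert f_tfidf_c_m(0.0, 7.0) == 0.0
        assert f_tfidf_c_m(0.0, 0.0) == 0.0

    def test_worked_value(self):
        assert f_tfidf_c_m(6.3399, 6.0) == pytest.approx(6.1653, abs=1e-4)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            f_tfidf_c_m(-1.0, 2.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(min_value=0, max_value=1e6, allow_nan=False),
        b=st.floats(min_value=0, max_value=1e6, allow_nan=False),
    )
    def test_bounds_and_symmetry(self, a, b):
        h = f_tfidf_c_m(a, b)
        assert min(a, b) - 1e-9 <= h <= max(a, b) + 1e-9
        assert h == pytest.approx(f_tfidf_c_m(b, a))


class TestRanking:
    def _stats(self, freq_table):
        cands = [make_candidate(lemmas, {"d1": f}) for lemmas, f in freq_table.items()]
        return score_candidates(cands, n_docs=2)

    def test_descending_scores_dense_ranks(self):
        stats = self._stats({("a",): 5, ("b",): 3, ("c",): 1})
        ranked = rank_terms(stats, C_VALUE)
        assert [r for _, _, r in ranked.entries] == [1, 2, 3]
        scores = [s for _, s, _ in ranked.entries]
        assert scores == sorted(scores, reverse=True)

    def test_tie_breaks_by_freq_then_lemma(self):
        cands = [
            make_candidate(("b",), {"d1": 5}),
            make_candidate(("a",), {"d1": 5}),
        ]
        stats = score_candidates(cands, n_docs=1)
        ranked = rank_terms(stats, C_VALUE)
        # equal score and freq: lexicographic lemma_key order decides
        assert ranked.terms() == ["a", "b"]

    def test_top_k_truncation(self):
        stats = self._stats({(chr(97 + i),): 10 - i for i in range(10)})
        assert len(rank_terms(stats, TFIDF, top_k=1)) == 1

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError):
            rank_terms([], "OKAPI")


class TestComposition:
    def _ranked(self, terms, measure=C_VALUE, source=""):
        entries = tuple((t, float(len(terms) - i), i + 1) for i, t in enumerate(terms))
        from bioterm.measures import RankedTermList

        return RankedTermList(measure=measure, entries=entries, source=source)

    def test_single_chunk_identity(self):
        lst = self._ranked(["x", "y", "z"])
        composed = compose_partition_ranks([lst])
        assert composed.terms() == ["x", "y", "z"]
        assert [s for _, s, _ in composed.entries] == [1.0, 2.0, 3.0]

    def test_mean_rank_arithmetic(self):
        # present at ranks 1 and 3 in two of three chunks -> mean 2.0, support 2
        chunks = [self._ranked(["t", "u"]), self._ranked(["v", "w", "t"]), self._ranked(["u", "v"])]
        composed = compose_partition_ranks(chunks)
        by_term = {t: (m, s) for t, m, s in composed.entries}
        assert by_term["t"] == (2.0, 2)

    def test_chunk_order_invariance(self):
        chunks = [self._ranked(["a", "b"]), self._ranked(["b", "c"]), self._ranked(["c", "a"])]
        forward = compose_partition_ranks(chunks)
        backward = compose_partition_ranks(list(reversed(chunks)))
        assert forward == backward

    def test_ascending_output(self):
        chunks = [self._ranked(["a", "b", "c"]), self._ranked(["c", "b", "a"])]
        composed = compose_partition_ranks(chunks)
        means = [m for _, m, _ in composed.entries]
        assert means == sorted(means)

    def test_mixed_measures_rejected(self):
        with pytest.raises(ValueError):
            compose_partition_ranks([self._ranked(["a"]), self._ranked(["a"], measure=TFIDF)])

    def test_score_basis_flag(self):
        chunks = [self._ranked(["a", "b"]), self._ranked(["b", "a"])]
        composed = compose_partition_ranks(chunks, on="score")
        by_term = {t: m for t, m, _ in composed.entries}
        assert by_term["a"] == pytest.approx(1.5)  # mean of scores 2 and 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_c_value_matches_direct_formula(self, seed):
        rng = random.Random(seed)
        cands = random_candidate_table(rng)
        nesting = compute_nesting(cands)
        freqs = {c.lemma_key: c.freq for c in cands}
        table = {c.lemmas: c.freq for c in cands}
        for cand in cands:
            assert c_value(cand, nesting, freqs) == pytest.approx(
                direct_c_value(cand.lemmas, table), abs=1e-9
            )
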