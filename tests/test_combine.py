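"""Intra-/inter-corpus set combinations and seed selection."""

import random

import pytest

from bioterm.combine import (
    inter_corpus_combination,
    intra_corpus_combination,
    overlap_percentages,
    select_driven_seeds,
)
from bioterm.lexicon import ReferenceLexicon
from bioterm.measures import C_VALUE, F_TFIDF_C_M, RankedTermList


def ranked(terms, measure=C_VALUE, source="title"):
    entries = tuple((t, float(len(terms) - i), i + 1) for i, t in enumerate(terms))
    return RankedTermList(measure=measure, entries=entries, source=source)


def random_lists(rng, k=10, universe=40):
    pool = [f"t{i}" for i in range(universe)]
    a = rng.sample(pool, k + rng.randint(0, 5))
    b = rng.sample(pool, k + rng.randint(0, 5))
    return ranked(a), ranked(b, measure=F_TFIDF_C_M)


class TestIntra:
    def test_identical_lists_all_common(self):
        cv = ranked(["a", "b", "c"])
        ft = ranked(["a", "b", "c"], measure=F_TFIDF_C_M)
        report = intra_corpus_combination(cv, ft, k=3)
        assert report.only_c_value == report.only_f_tfidf == frozenset()
        assert report.common == {"a", "b", "c"}

    def test_disjoint_lists_no_common(self):
        report = intra_corpus_combination(
            ranked(["a", "b"]), ranked(["c", "d"], measure=F_TFIDF_C_M), k=2
        )
        assert report.common == frozenset()
        assert len(report.only_c_value) == len(report.only_f_tfidf) == 2

    def test_partial_overlap_set_arithmetic(self):
        report = intra_corpus_combination(
            ranked(["a", "b", "c"]), ranked(["c", "d", "e"], measure=F_TFIDF_C_M), k=3
        )
        assert report.only_c_value == {"a", "b"}
        assert report.only_f_tfidf == {"d", "e"}
        assert report.common == {"c"}

    def test_mismatched_corpus_labels_rejected(self):
        with pytest.raises(ValueError, match="label"):
            intra_corpus_combination(
                ranked(["a"], source="title"),
                ranked(["a"], measure=F_TFIDF_C_M, source="abstract"),
                k=1,
            )

    def test_lexicon_annotation_covers_union(self):
        lex = ReferenceLexicon.from_terms(["aa bb"])
        report = intra_corpus_combination(
            ranked(["aa bb", "cc dd"]), ranked(["cc dd", "ee ff"], measure=F_TFIDF_C_M),
            lexicon=lex, k=2,
        )
        assert set(report.lexicon_annotation) == report.all_terms

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_identities_on_random_lists(self, seed):
        rng = random.Random(seed)
        cv, ft = random_lists(rng)
        report = intra_corpus_combination(cv, ft, k=10)
        a, b, c = report.only_c_value, report.only_f_tfidf, report.common
        assert not (a & b) and not (a & c) and not (b & c)
        assert a | b | c == set(cv.terms(10)) | set(ft.terms(10))

    @pytest.mark.parametrize("seed", range(4))
    def test_measure_swap_symmetry(self, seed):
        rng = random.Random(seed)
        cv, ft = random_lists(rng)
        fwd = intra_corpus_combination(cv, ft, k=10)
        swapped = intra_corpus_combination(
            RankedTermList(C_VALUE, ft.entries, ft.source),
            RankedTermList(F_TFIDF_C_M, cv.entries, cv.source),
            k=10,
        )
        assert fwd.only_c_value == swapped.only_f_tfidf
        assert fwd.only_f_tfidf == swapped.only_c_value
        assert fwd.common == swapped.common

    def test_common_monotone_in_k(self):
        rng = random.Random(99)
        cv, ft = random_lists(rng, k=8, universe=20)
        for k in range(1, 8):
            small = intra_corpus_combination(cv, ft, k=k).common
            large = intra_corpus_combination(cv, ft, k=k + 1).common
            assert small <= large


def three_segments(t, a, c, measure=C_VALUE):
    return {
        "title": ranked(t, measure, "title"),
        "abstract": ranked(a, measure, "abstract"),
        "content": ranked(c, measure, "content"),
    }


class TestInter:
    def test_identical_sets_all_common(self):
        report = inter_corpus_combination(three_segments(["x", "y"], ["x", "y"], ["x", "y"]), k=2)
        assert report.common == {"x", "y"}
        assert all(not d for d in report.discriminants.values())

    def test_disjoint_sets_all_discriminant(self):
        report = inter_corpus_combination(three_segments(["a"], ["b"], ["c"]), k=1)
        assert report.common == frozenset()
        assert report.discriminants == {
            "title": {"a"}, "abstract": {"b"}, "content": {"c"},
        }

    def test_star_overlap_arithmetic(self):
        report = inter_corpus_combination(
            three_segments(["x", "y"], ["x", "z"], ["x", "w"]), k=2
        )
        assert report.common == {"x"}
        assert report.set_ta == {"x"} and report.set_tc == {"x"}
        assert report.discriminants == {
            "title": {"y"}, "abstract": {"z"}, "content": {"w"},
        }

    def test_subset_chains(self):
        rng = random.Random(3)
        pool = [f"t{i}" for i in range(30)]
        segs = three_segments(
            rng.sample(pool, 12), rng.sample(pool, 12), rng.sample(pool, 12)
        )
        report = inter_corpus_combination(segs, k=12)
        t = report.segment_sets["title"]
        assert report.common <= report.set_ta <= t
        assert report.common <= report.set_tc <= t
        discs = list(report.discriminants.values())
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (discs[i] & discs[j])
            assert not (discs[i] & report.common)

    def test_measure_mismatch_rejected(self):
        segs = three_segments(["a"], ["b"], ["c"])
        segs["content"] = ranked(["c"], F_TFIDF_C_M, "content")
        with pytest.raises(ValueError, match="measure"):
            inter_corpus_combination(segs, k=1)

    def test_missing_segment_rejected(self):
        segs = three_segments(["a"], ["b"], ["c"])
        del segs["abstract"]
        with pytest.raises(ValueError, match="abstract"):
            inter_corpus_combination(segs, k=1)


class TestOverlapPercentages:
    def test_half_overlap(self):
        report = inter_corpus_combination(
            three_segments(["a", "b", "c", "d"], ["a", "b", "x", "y"], ["p", "q", "r", "s"]),
            k=4,
        )
        pct = overlap_percentages(report)
        assert pct["title_in_abstract"] == 50
        assert pct["title_in_content"] == 0
        assert pct["common"] == 0

    def test_full_containment(self):
        report = inter_corpus_combination(
            three_segments(["a", "b"], ["a", "b"], ["c", "d"]), k=2
        )
        assert overlap_percentages(report)["title_in_abstract"] == 100

    def test_rounding_half_up(self):
        # 1 of 3 = 33.33 -> 33; 2 of 3 = 66.67 -> 67
        report = inter_corpus_combination(
            three_segments(["a", "b", "c"], ["a", "b", "x"], ["y", "z", "w"]), k=3
        )
        assert overlap_percentages(report)["title_in_abstract"] == 67


class TestSeedSelection:
    def test_common_strategy(self):
        report = inter_corpus_combination(
            three_segments(["x", "y"], ["x", "z"], ["x", "w"]), k=2
        )
        seeds = select_driven_seeds(report, "common")
        assert [s.surface for s in seeds] == ["x"]

    def test_discriminant_strategy(self):
        report = inter_corpus_combination(
            three_segments(["x", "y"], ["x", "z"], ["x", "w"]), k=2
        )
        seeds = select_driven_seeds(report, "discriminant", segment="title")
        assert [s.surface for s in seeds] == ["y"]

    def test_empty_common_warns_and_returns_empty(self, caplog):
        report = inter_corpus_combination(three_segments(["a"], ["b"], ["c"]), k=1)
        assert select_driven_seeds(report, "common") == []

    def test_unknown_strategy_rejected(self):
        report = inter_corpus_combination(three_segments(["a"], ["b"], ["c"]), k=1)
        with pytest.raises(ValueError):
            select_driven_seeds(report, "bogus")
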