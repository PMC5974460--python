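"""Query construction, BM25 retrieval, agreement and coverage."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from needgap.cli import _query_topics
from needgap.gap import (
    Query,
    QueryError,
    RatingRow,
    RatingTable,
    RetrievalResult,
    bm25_rank,
    build_queries,
    build_query,
    coverage,
    gap_report,
    index_pages,
    percent_agreement,
    read_queries,
    resolve_reference,
    select_need_sentences,
    write_queries,
)
from needgap.synth import (
    EducationConfig,
    GeneratorConfig,
    LengthDistribution,
    RaterConfig,
    generate_corpus,
    generate_education_pages,
    simulate_raters,
)

from conftest import build_corpus


# --------------------------------------------------------------------------
# need-sentence selection

def test_duplicate_previous_after_need_removed():
    corpus = build_corpus([[[
        ("I am concerned about insurance for taxol.", {"other"}, True),
        ("Any answers out there?", {"previous"}, True),
    ]]])
    selected = select_need_sentences(corpus)
    assert [s.index_in_post for s in selected] == [0]


def test_previous_not_after_need_retained():
    corpus = build_corpus([[[
        ("I had chemo last spring.", {"medical"}, False),
        ("Anyone else have this difficulty?", {"previous"}, True),
    ]]])
    assert len(select_need_sentences(corpus)) == 1


def test_no_need_sentences_gives_empty_list(toy_corpus):
    corpus = build_corpus([[[("hello there.", {"social"}, False)]]])
    assert select_need_sentences(corpus) == []


# --------------------------------------------------------------------------
# referential resolution

def test_resolution_prefers_nearest_nonsocial():
    corpus = build_corpus([[[
        ("The chemo gave me headaches.", {"medical"}, False),
        ("Thanks everyone for the support.", {"social"}, False),
        ("Anyone else have this?", {"previous"}, True),
    ]]])
    target, warned = resolve_reference(list(corpus.sentences())[2], corpus)
    assert target.index_in_post == 0 and not warned


def test_resolution_immediate_antecedent():
    corpus = build_corpus([[[
        ("The radiation burned my skin.", {"physical"}, False),
        ("Is this normal?", {"previous"}, True),
    ]]])
    target, _ = resolve_reference(list(corpus.sentences())[1], corpus)
    assert target.index_in_post == 0


def test_resolution_tie_prefers_preceding():
    corpus = build_corpus([[[
        ("My oncologist suggested chemo.", {"medical"}, False),
        ("What about this?", {"previous"}, True),
        ("The pain kept me awake.", {"physical"}, False),
    ]]])
    target, _ = resolve_reference(list(corpus.sentences())[1], corpus)
    assert target.index_in_post == 0


def test_resolution_all_social_falls_back_with_warning():
    corpus = build_corpus([[[
        ("Hugs to everyone.", {"social"}, False),
        ("Anyone else feel this?", {"previous"}, True),
    ]]])
    sent = list(corpus.sentences())[1]
    with pytest.warns(UserWarning, match="no non-social antecedent"):
        target, warned = resolve_reference(sent, corpus)
    assert warned and target == sent


# --------------------------------------------------------------------------
# query construction

def _toy_index(texts):
    return index_pages((f"page{i:02d}", t) for i, t in enumerate(texts))


def test_query_caps_at_ten_terms():
    words = [f"term{i}" for i in range(12)]
    corpus = build_corpus([[[(" ".join(words) + "?", {"medical"}, True)]]])
    index = _toy_index(["filler text"])
    q = build_query(list(corpus.sentences())[0], index)
    assert len(q.terms) == 10


def test_query_tfidf_ordering_hand_computed():
    # chemo appears in 9 of 10 pages, fatigue in 1; despite tf(chemo)=2 the
    # rare term wins: 1*(ln(11/2)+1) = 2.705 > 2*(ln(11/10)+1) = 2.191
    texts = ["chemo treatment"] * 9 + ["fatigue clinic"]
    index = _toy_index(texts)
    corpus = build_corpus([[[("chemo chemo fatigue?", {"medical"}, True)]]])
    q = build_query(list(corpus.sentences())[0], index)
    w = dict(q.terms)
    assert w["chemo"] == pytest.approx(2 * (math.log(11 / 10) + 1))
    assert w["fatigue"] == pytest.approx(math.log(11 / 2) + 1)
    assert [t for t, _ in q.terms] == ["fatigue", "chemo"]


def test_query_tie_breaks_alphabetically():
    index = _toy_index(["unrelated words"])
    corpus = build_corpus([[[("zebra apple?", {"medical"}, True)]]])
    q = build_query(list(corpus.sentences())[0], index)
    assert [t for t, _ in q.terms] == ["apple", "zebra"]


def test_all_stopword_sentence_rejected():
    index = _toy_index(["some page"])
    corpus = build_corpus([[[("how do i do it?", {"medical"}, True)]]])
    with pytest.raises(QueryError, match="no content terms"):
        build_query(list(corpus.sentences())[0], index)


def test_previous_query_uses_only_antecedent_terms():
    corpus = build_corpus([[[
        ("The chemo caused neuropathy.", {"medical"}, False),
        ("Thanks for listening everyone.", {"social"}, False),
        ("Has anyone tried acupuncture for this problem?", {"previous"}, True),
    ]]])
    index = _toy_index(["chemo neuropathy care"])
    sent = list(corpus.sentences())[2]
    q = build_query(sent, index, corpus=corpus)
    assert q.resolved_sentence_id != q.source_sentence_id
    assert set(dict(q.terms)) == {"chemo", "caused", "neuropathy"}


def test_query_files_byte_identical(tmp_path):
    corpus = build_corpus([[[
        ("chemo pain question?", {"medical"}, True),
        ("radiation advice needed?", {"medical"}, True),
    ]]])
    index = _toy_index(["chemo radiation pain"])
    for name in ("a.csv", "b.csv"):
        write_queries(build_queries(corpus, index), tmp_path / name)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    assert len(read_queries(tmp_path / "a.csv")) == 2


# --------------------------------------------------------------------------
# page index

def test_identical_pages_share_statistics():
    index = _toy_index(["chemo pain relief", "chemo pain relief"])
    assert index.n_pages == 2
    assert index.df == {"chemo": 2, "pain": 2, "relief": 2}
    lengths = [length for _, _, length in index.pages]
    assert lengths == [3, 3] and index.avgdl == 3.0


def test_hand_counts_three_pages():
    index = _toy_index(["a b a", "b c", "c c c c"])
    assert index.df == {"a": 1, "b": 2, "c": 2}
    assert index.avgdl == pytest.approx((3 + 2 + 4) / 3)


def test_punctuation_only_page_excluded_with_warning():
    with pytest.warns(UserWarning, match="no tokens"):
        index = index_pages([("p0", "real words here"), ("p1", "... !!!")])
    assert index.n_pages == 1


def test_empty_collection_rejected(tmp_path):
    with pytest.raises(ValueError, match="no non-empty pages"):
        index_pages([])
    with pytest.raises(FileNotFoundError):
        index_pages(tmp_path / "missing_dir")


def test_directory_indexing(tmp_path):
    (tmp_path / "b.txt").write_text("second page text")
    (tmp_path / "a.txt").write_text("first page text")
    index = index_pages(tmp_path)
    assert [pid for pid, _, _ in index.pages] == ["a", "b"]


# --------------------------------------------------------------------------
# BM25

def _query(terms):
    return Query("q", "s", "s", tuple((t, 1.0) for t in terms))


def bm25_reference(terms, pages, k1=1.2, b=0.75):
    """Independent evaluation of the scoring formula from token lists."""
    from collections import Counter

    counts = [Counter(p) for p in pages]
    n = len(pages)
    avgdl = sum(len(p) for p in pages) / n
    scores = []
    for c, p in zip(counts, pages):
        s = 0.0
        for t in set(terms):
            df = sum(1 for cc in counts if t in cc)
            f = c[t]
            if f:
                idf = math.log(1 + (n - df + 0.5) / (df + 0.5))
                s += idf * f * (k1 + 1) / (f + k1 * (1 - b + b * len(p) / avgdl))
        scores.append(s)
    return scores


def test_absent_term_scores_zero_everywhere():
    index = _toy_index(["alpha beta", "gamma delta"])
    result = bm25_rank(_query(["missing"]), index)
    assert all(score == 0.0 for _, score in result.ranked)


def test_single_matching_page_ranks_first():
    index = _toy_index(["nothing here", "chemo advice page"])
    result = bm25_rank(_query(["chemo"]), index)
    assert result.ranked[0][0] == "page01"
    assert result.ranked[0][1] > result.ranked[1][1]


def test_ties_break_by_page_id():
    index = _toy_index(["same text", "same text"])
    result = bm25_rank(_query(["same"]), index)
    assert [pid for pid, _ in result.ranked] == ["page00", "page01"]


def test_bm25_matches_reference_on_random_instances():
    rng = np.random.default_rng(13)
    vocab = ["chemo", "pain", "diet", "scan", "hope", "rest", "walk"]
    for _ in range(50):
        n_pages = int(rng.integers(1, 6))
        pages = [[vocab[j] for j in rng.integers(0, len(vocab), rng.integers(1, 12))]
                 for _ in range(n_pages)]
        terms = [vocab[j] for j in rng.integers(0, len(vocab), rng.integers(1, 6))]
        index = index_pages((f"page{i:02d}", " ".join(p)) for i, p in enumerate(pages))
        result = bm25_rank(_query(terms), index, top_k=n_pages)
        expected = bm25_reference(terms, pages)
        got = dict(result.ranked)
        for i, exp in enumerate(expected):
            assert got[f"page{i:02d}"] == pytest.approx(exp)
        scores = [s for _, s in result.ranked]
        assert scores == sorted(scores, reverse=True)


# --------------------------------------------------------------------------
# agreement and coverage

def _table(rows):
    return RatingTable(tuple(RatingRow(*r) for r in rows))


def test_identical_raters_agree_fully():
    table = _table([("q1", "p1", "r1", True), ("q1", "p1", "r2", True),
                    ("q1", "p2", "r1", False), ("q1", "p2", "r2", False)])
    agreement, per_rater, flagged = percent_agreement(table)
    assert agreement == 1.0 and not flagged
    assert per_rater == {"r1": 0.5, "r2": 0.5}


def test_complementary_raters_agree_never():
    table = _table([("q1", "p1", "r1", True), ("q1", "p1", "r2", False),
                    ("q1", "p2", "r1", False), ("q1", "p2", "r2", True)])
    agreement, _, _ = percent_agreement(table)
    assert agreement == 0.0


def test_missing_verdict_is_an_error():
    table = _table([("q1", "p1", "r1", True), ("q1", "p2", "r1", False),
                    ("q1", "p2", "r2", True)])
    with pytest.raises(ValueError, match="missing verdicts"):
        percent_agreement(table)


def test_three_raters_use_flagged_pairwise_mean():
    table = _table([("q1", "p1", "r1", True), ("q1", "p1", "r2", True),
                    ("q1", "p1", "r3", False)])
    agreement, _, flagged = percent_agreement(table)
    assert flagged and agreement == pytest.approx(1 / 3)


def test_duplicate_rating_row_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        _table([("q1", "p1", "r1", True), ("q1", "p1", "r1", False)])


def test_coverage_trivial_cases():
    full = _table([("q1", "p1", "r1", True), ("q1", "p1", "r2", True)])
    assert coverage(full) == (1.0, 1.0)
    none = _table([("q1", "p1", "r1", False), ("q1", "p1", "r2", False)])
    assert coverage(none) == (0.0, 0.0)


def test_coverage_any_counts_split_verdicts():
    table = _table([
        ("q1", "p1", "r1", True), ("q1", "p1", "r2", False),   # any, not all
        ("q2", "p2", "r1", False), ("q2", "p2", "r2", False),  # neither
    ])
    assert coverage(table) == (0.5, 0.0)


def test_coverage_all_needs_one_document_relevant_to_all():
    # each rater likes a different document: any-covered but not all-covered
    table = _table([
        ("q1", "p1", "r1", True), ("q1", "p1", "r2", False),
        ("q1", "p2", "r1", False), ("q1", "p2", "r2", True),
    ])
    assert coverage(table) == (1.0, 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.integers(0, 5), st.booleans(), st.booleans()),
    min_size=1, max_size=30, unique_by=lambda r: r[0],
))
def test_coverage_all_never_exceeds_coverage_any(rows):
    table = _table([(f"q{q}", "p1", "r1", a) for q, a, _ in rows]
                   + [(f"q{q}", "p1", "r2", b) for q, _, b in rows])
    cov_any, cov_all = coverage(table)
    assert 0.0 <= cov_all <= cov_any <= 1.0


def test_gap_report_consistency():
    table = _table([
        ("q1", "p1", "r1", True), ("q1", "p1", "r2", True),
        ("q2", "p2", "r1", True), ("q2", "p2", "r2", False),
        ("q3", "p3", "r1", False), ("q3", "p3", "r2", False),
    ])
    report = gap_report(table)
    assert report.n_documents_rated == 3
    assert report.coverage_any == pytest.approx(2 / 3)
    assert report.coverage_all == pytest.approx(1 / 3)
    assert report.percent_agreement == pytest.approx(2 / 3)


# --------------------------------------------------------------------------
# end-to-end coverage recovery (balanced topics, perfect raters)

def balanced_config(seed):
    topics = ["medical", "physical", "psychological", "background",
              "wellness", "resource", "other"]
    return GeneratorConfig(
        seed=seed,
        n_sentences=900,
        posts_per_conversation=LengthDistribution(3, 1),
        sentences_per_post=LengthDistribution(6, 2),
        words_per_sentence=LengthDistribution(11, 3),
        category_mixture={t: 1 / 7 for t in topics[:-1]}
        | {"other": 1 - 6 / 7},
        hasn_rate_by_category={t: 0.35 for t in topics},
    )


def test_perfect_raters_recover_planted_coverage():
    gconfig = balanced_config(17)
    corpus = generate_corpus(gconfig)
    pages, gold = generate_education_pages(
        EducationConfig(seed=17, coverage_fraction=0.3, n_pages=30), gconfig)
    index = index_pages(pages)
    queries = build_queries(corpus, index)
    assert len(queries) > 100
    results = [bm25_rank(q, index) for q in queries]
    table = simulate_raters(results, gold, RaterConfig(seed=17),
                            _query_topics(corpus, queries))
    _cov_any, cov_all = coverage(table, n_queries=len(queries))
    assert cov_all == pytest.approx(0.3, abs=0.1)
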