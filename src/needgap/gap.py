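"""Knowledge-gap assessment: from need sentences to rated retrieval results.

Pipeline: (1) index each education page as one retrieval unit; (2) select
the sentences expressing an information need, dropping duplicates (a
"previous" sentence that immediately follows another need sentence restates
it); (3) for referential sentences, pull terms from the nearest sentence
with a non-social information category; (4) build a query of up to ten
content terms ranked by tf-idf after stop-word removal; (5) rank pages with
Okapi BM25 and keep the top two; (6) from per-document rater verdicts,
compute simple percent agreement and the fraction of queries covered by at
least one rater (coverage-any) and by all raters (coverage-all).  The
complement of coverage estimates the knowledge gap.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Corpus, Sentence, tokenize

_DEFAULT_STOPLIST_PATH = Path(__file__).parent / "data" / "stopwords.txt"
_STOPLIST: frozenset[str] | None = None

MAX_QUERY_TERMS = 10
DEFAULT_TOP_K = 2


class QueryError(ValueError):
    """A need sentence yields no usable query terms."""


def default_stoplist() -> frozenset[str]:
    global _STOPLIST
    if _STOPLIST is None:
        lines = _DEFAULT_STOPLIST_PATH.read_text(encoding="utf-8").splitlines()
        _STOPLIST = frozenset(
            ln.strip().lower() for ln in lines if ln.strip() and not ln.startswith("#")
        )
    return _STOPLIST


# --------------------------------------------------------------------------
# need-sentence selection and referential resolution

def select_need_sentences(corpus: Corpus) -> list[Sentence]:
    """All HASN sentences minus duplicates.

    A duplicate is a sentence labelled "previous" that immediately follows
    (same post, adjacent index) another sentence flagged as expressing a
    need: it restates that need rather than adding a new one.
    """
    selected: list[Sentence] = []
    for post in corpus.posts():
        for i, s in enumerate(post.sentences):
            if not s.hasn:
                continue
            if "previous" in s.categories and i > 0 and post.sentences[i - 1].hasn:
                continue
            selected.append(s)
    return selected


def resolve_reference(sentence: Sentence, corpus: Corpus) -> tuple[Sentence, bool]:
    """Source sentence for the terms of a referential ("previous") need.

    Returns the nearest sentence in the conversation (absolute sentence
    distance; ties prefer the preceding one) that carries at least one
    category other than social/previous.  If the conversation has none, the
    sentence itself is returned with ``warned=True``.
    """
    conv = next(c for c in corpus.conversations
                if c.conversation_id == sentence.conversation_id)
    flat = list(conv.sentences())
    pos = next(i for i, s in enumerate(flat) if s.sentence_id == sentence.sentence_id)
    best: Sentence | None = None
    best_key: tuple[int, int] | None = None
    for i, s in enumerate(flat):
        if i == pos:
            continue
        if not (s.categories - {"social", "previous"}):
            continue
        # ties in distance resolve toward the preceding sentence
        key = (abs(i - pos), 0 if i < pos else 1)
        if best_key is None or key < best_key:
            best, best_key = s, key
    if best is None:
        warnings.warn(
            f"no non-social antecedent for {sentence.sentence_id}; using the sentence itself"
        )
        return sentence, True
    return best, False


# --------------------------------------------------------------------------
# page index

@dataclass(frozen=True)
class PageIndex:
    """Per-page token counts plus collection statistics for BM25."""

    pages: tuple[tuple[str, Mapping[str, int], int], ...]  # (page_id, counts, length)
    df: Mapping[str, int]
    avgdl: float
    k1: float = 1.2
    b: float = 0.75

    @property
    def n_pages(self) -> int:
        return len(self.pages)

    def document_frequency(self, term: str) -> int:
        return self.df.get(term, 0)


def index_pages(source: str | Path | Iterable[tuple[str, str]],
                k1: float = 1.2, b: float = 0.75) -> PageIndex:
    """Index whole pages from a directory of ``.txt`` files (sorted by name)
    or from an iterable of ``(page_id, text)`` pairs.

    Tokenization matches the corpus tokenizer.  Pages with no tokens are
    excluded with a warning; an empty collection is an error.
    """
    if isinstance(source, (str, Path)):
        directory = Path(source)
        if not directory.is_dir():
            raise FileNotFoundError(f"page directory not found: {directory}")
        items = [(p.stem, p.read_text(encoding="utf-8"))
                 for p in sorted(directory.glob("*.txt"))]
    else:
        items = list(source)
    pages: list[tuple[str, Mapping[str, int], int]] = []
    df: Counter = Counter()
    for page_id, text in items:
        tokens = tokenize(text)
        if not tokens:
            warnings.warn(f"page {page_id!r} has no tokens; excluded from the index")
            continue
        counts = Counter(tokens)
        pages.append((page_id, dict(counts), len(tokens)))
        df.update(counts.keys())
    if not pages:
        raise ValueError("no non-empty pages to index")
    avgdl = sum(length for _, _, length in pages) / len(pages)
    return PageIndex(tuple(pages), dict(df), avgdl, k1, b)


def write_index(index: PageIndex, path: str | Path) -> None:
    payload = {
        "k1": index.k1, "b": index.b, "avgdl": index.avgdl,
        "pages": [{"page_id": pid, "counts": counts, "length": length}
                  for pid, counts, length in index.pages],
    }
    Path(path).write_text(json.dumps(payload) + "\n", encoding="utf-8")


def read_index(path: str | Path) -> PageIndex:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    pages = tuple((p["page_id"], p["counts"], p["length"]) for p in payload["pages"])
    df: Counter = Counter()
    for _, counts, _ in pages:
        df.update(counts.keys())
    return PageIndex(pages, dict(df), payload["avgdl"], payload["k1"], payload["b"])


# --------------------------------------------------------------------------
# query construction

@dataclass(frozen=True)
class Query:
    query_id: str
    source_sentence_id: str
    resolved_sentence_id: str
    terms: tuple[tuple[str, float], ...]  # (term, tf-idf weight), descending

    def __post_init__(self) -> None:
        if not 1 <= len(self.terms) <= MAX_QUERY_TERMS:
            raise ValueError(f"query carries 1-{MAX_QUERY_TERMS} terms, got {len(self.terms)}")


def _idf_counts(idf_source: PageIndex | Corpus) -> tuple[int, Mapping[str, int]]:
    if isinstance(idf_source, PageIndex):
        return idf_source.n_pages, idf_source.df
    df: Counter = Counter()
    n = 0
    for s in idf_source.sentences():
        n += 1
        df.update(set(s.tokens))
    return n, df


def build_query(sentence: Sentence, idf_source: PageIndex | Corpus,
                stoplist: frozenset[str] | None = None,
                k: int = MAX_QUERY_TERMS,
                corpus: Corpus | None = None) -> Query:
    """Up to ``k`` content terms from the (resolved) sentence, by tf-idf.

    For a referential sentence the terms come exclusively from its resolved
    antecedent (``corpus`` required).  tf is the raw term count in the
    sentence; idf = ln((N + 1) / (df + 1)) + 1 over the chosen collection
    (the education-page index by default, a forum corpus as the switch).
    Ties break alphabetically.  A sentence whose tokens are all stop-words
    raises :class:`QueryError`.
    """
    if stoplist is None:
        stoplist = default_stoplist()
    resolved = sentence
    if "previous" in sentence.categories:
        if corpus is None:
            raise ValueError("resolving a referential sentence requires the corpus")
        resolved, _ = resolve_reference(sentence, corpus)
    content = [t for t in resolved.tokens if t not in stoplist]
    if not content:
        raise QueryError(
            f"sentence {sentence.sentence_id} (resolved {resolved.sentence_id}) "
            "has no content terms after stop-word removal"
        )
    n_docs, df = _idf_counts(idf_source)
    tf = Counter(content)
    scored = sorted(
        ((term, count * (math.log((n_docs + 1) / (df.get(term, 0) + 1)) + 1))
         for term, count in tf.items()),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return Query(
        query_id=sentence.sentence_id,
        source_sentence_id=sentence.sentence_id,
        resolved_sentence_id=resolved.sentence_id,
        terms=tuple(scored[:k]),
    )


def build_queries(corpus: Corpus, idf_source: PageIndex | Corpus,
                  stoplist: frozenset[str] | None = None,
                  k: int = MAX_QUERY_TERMS) -> list[Query]:
    """Queries for every selected need sentence; sentences with no content
    terms are skipped with a warning."""
    queries = []
    for s in select_need_sentences(corpus):
        try:
            queries.append(build_query(s, idf_source, stoplist, k, corpus=corpus))
        except QueryError as exc:
            warnings.warn(str(exc))
    return queries


# --------------------------------------------------------------------------
# BM25 ranking

@dataclass(frozen=True)
class RetrievalResult:
    query_id: str
    ranked: tuple[tuple[str, float], ...]  # (page_id, score), non-increasing

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranked]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("retrieval scores must be non-increasing")


def bm25_idf(n_pages: int, df: int) -> float:
    return math.log(1.0 + (n_pages - df + 0.5) / (df + 0.5))


def bm25_score(query_terms: Iterable[str], counts: Mapping[str, int],
               length: int, index: PageIndex) -> float:
    score = 0.0
    for term in dict.fromkeys(query_terms):  # each distinct term scores once
        f = counts.get(term, 0)
        if f == 0:
            continue
        idf = bm25_idf(index.n_pages, index.document_frequency(term))
        denom = f + index.k1 * (1.0 - index.b + index.b * length / index.avgdl)
        score += idf * f * (index.k1 + 1.0) / denom
    return score


def bm25_rank(query: Query, index: PageIndex, top_k: int = DEFAULT_TOP_K) -> RetrievalResult:
    """Okapi BM25 ranking of the indexed pages; ties break by page id."""
    terms = [t for t, _w in query.terms]
    scored = [(page_id, bm25_score(terms, counts, length, index))
              for page_id, counts, length in index.pages]
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return RetrievalResult(query.query_id, tuple(scored[:top_k]))


# --------------------------------------------------------------------------
# ratings, agreement and coverage

@dataclass(frozen=True)
class RatingRow:
    query_id: str
    page_id: str
    rater_id: str
    relevant: bool


@dataclass(frozen=True)
class RatingTable:
    rows: tuple[RatingRow, ...]

    def __post_init__(self) -> None:
        keys = [(r.query_id, r.page_id, r.rater_id) for r in self.rows]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (query, page, rater) rows in rating table")

    @property
    def raters(self) -> list[str]:
        return sorted({r.rater_id for r in self.rows})

    def documents(self) -> dict[tuple[str, str], dict[str, bool]]:
        """Verdicts grouped per rated document (query, page)."""
        docs: dict[tuple[str, str], dict[str, bool]] = {}
        for r in self.rows:
            docs.setdefault((r.query_id, r.page_id), {})[r.rater_id] = r.relevant
        return docs


@dataclass(frozen=True)
class GapReport:
    n_queries: int
    n_documents_rated: int
    percent_agreement: float
    per_rater_relevant_fraction: Mapping[str, float]
    coverage_any: float
    coverage_all: float
    pairwise_flag: bool = False  # True when >2 raters forced a pairwise mean


def percent_agreement(ratings: RatingTable) -> tuple[float, dict[str, float], bool]:
    """Simple (chance-uncorrected) agreement over rated documents.

    With two raters: the fraction of documents with identical verdicts.
    With more, the mean over rater pairs, flagged.  Also returns each
    rater's fraction of documents marked relevant.  A document missing any
    rater's verdict is an error.
    """
    raters = ratings.raters
    if len(raters) < 2:
        raise ValueError("agreement needs at least two raters")
    docs = ratings.documents()
    missing = [(q, p, r) for (q, p), verdicts in sorted(docs.items())
               for r in raters if r not in verdicts]
    if missing:
        raise ValueError(f"missing verdicts for (query, page, rater): {missing[:5]}")
    n_docs = len(docs)
    per_rater = {
        r: sum(1 for verdicts in docs.values() if verdicts[r]) / n_docs for r in raters
    }
    pair_scores = []
    for r1, r2 in combinations(raters, 2):
        agree = sum(1 for verdicts in docs.values() if verdicts[r1] == verdicts[r2])
        pair_scores.append(agree / n_docs)
    return sum(pair_scores) / len(pair_scores), per_rater, len(raters) > 2


def coverage(ratings: RatingTable, n_queries: int | None = None) -> tuple[float, float]:
    """(coverage_any, coverage_all) over queries.

    coverage_any: fraction of queries where >= 1 rated document was marked
    relevant by >= 1 rater.  coverage_all: fraction where some single
    document was marked relevant by every rater.
    """
    docs = ratings.documents()
    queries = sorted({q for q, _p in docs})
    if n_queries is None:
        n_queries = len(queries)
    elif n_queries < len(queries):
        raise ValueError(f"n_queries={n_queries} < {len(queries)} distinct rated queries")
    if n_queries == 0:
        return 0.0, 0.0
    any_hit = all_hit = 0
    for q in queries:
        verdict_sets = [v for (qq, _p), v in docs.items() if qq == q]
        if any(any(v.values()) for v in verdict_sets):
            any_hit += 1
        if any(all(v.values()) for v in verdict_sets):
            all_hit += 1
    return any_hit / n_queries, all_hit / n_queries


def gap_report(ratings: RatingTable, n_queries: int | None = None) -> GapReport:
    agreement, per_rater, flagged = percent_agreement(ratings)
    docs = ratings.documents()
    cov_any, cov_all = coverage(ratings, n_queries)
    return GapReport(
        n_queries=n_queries if n_queries is not None else len({q for q, _ in docs}),
        n_documents_rated=len(docs),
        percent_agreement=agreement,
        per_rater_relevant_fraction=per_rater,
        coverage_any=cov_any,
        coverage_all=cov_all,
        pairwise_flag=flagged,
    )


# --------------------------------------------------------------------------
# file I/O

def write_queries(queries: Sequence[Query], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query_id", "source_sentence_id", "resolved_sentence_id", "terms"])
        for q in queries:
            terms = "|".join(f"{t}:{w:.6f}" for t, w in q.terms)
            writer.writerow([q.query_id, q.source_sentence_id, q.resolved_sentence_id, terms])


def read_queries(path: str | Path) -> list[Query]:
    queries = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            terms = tuple(
                (part.rsplit(":", 1)[0], float(part.rsplit(":", 1)[1]))
                for part in row["terms"].split("|") if part
            )
            queries.append(Query(row["query_id"], row["source_sentence_id"],
                                 row["resolved_sentence_id"], terms))
    return queries


def write_results(results: Sequence[RetrievalResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query_id", "rank", "page_id", "score"])
        for res in results:
            for rank, (page_id, score) in enumerate(res.ranked, start=1):
                writer.writerow([res.query_id, rank, page_id, f"{score:.6f}"])


def write_ratings(ratings: RatingTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query_id", "page_id", "rater_id", "relevant"])
        for r in ratings.rows:
            writer.writerow([r.query_id, r.page_id, r.rater_id, int(r.relevant)])


def read_ratings(path: str | Path) -> RatingTable:
    rows = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(RatingRow(row["query_id"], row["page_id"], row["rater_id"],
                                  row["relevant"].strip() in {"1", "true", "True"}))
    return RatingTable(tuple(rows))


def write_gap_report(report: GapReport, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["statistic", "value"])
        writer.writerow(["n_queries", report.n_queries])
        writer.writerow(["n_documents_rated", report.n_documents_rated])
        writer.writerow(["percent_agreement", f"{report.percent_agreement:.4f}"])
        for rater, frac in sorted(report.per_rater_relevant_fraction.items()):
            writer.writerow([f"relevant_fraction_{rater}", f"{frac:.4f}"])
        writer.writerow(["coverage_any", f"{report.coverage_any:.4f}"])
        writer.writerow(["coverage_all", f"{report.coverage_all:.4f}"])
    text = (
        f"Queries: {report.n_queries}\n"
        f"Documents rated: {report.n_documents_rated}\n"
        f"Percent agreement: {100 * report.percent_agreement:.1f}%\n"
        f"Coverage by at least one rater: {100 * report.coverage_any:.1f}%\n"
        f"Coverage by all raters: {100 * report.coverage_all:.1f}%\n"
        f"Estimated knowledge gap (all-rater): {100 * (1 - report.coverage_all):.1f}%\n"
    )
    path.with_suffix(".txt").write_text(text, encoding="utf-8")


def write_review_file(queries: Sequence[Query], results: Sequence[RetrievalResult],
                      corpus: Corpus, pages: Mapping[str, str], path: str | Path) -> None:
    """Markdown review sheet for human raters: the full posting with the
    query sentence highlighted, then each retrieved page with query terms
    marked."""
    by_id = corpus.sentence_by_id()
    res_by_query = {r.query_id: r for r in results}
    posts = {(p.conversation_id, p.post_id): p for p in corpus.posts()}
    lines: list[str] = ["# Retrieval review", ""]
    for q in queries:
        s = by_id[q.source_sentence_id]
        lines.append(f"## Query {q.query_id}")
        lines.append("")
        lines.append("Posting (query sentence in bold):")
        lines.append("")
        post = posts[(s.conversation_id, s.post_id)]
        for sent in post.sentences:
            mark = "**" if sent.sentence_id == s.sentence_id else ""
            lines.append(f"> {mark}{sent.text}{mark}")
        lines.append("")
        lines.append("Query terms: " + ", ".join(t for t, _ in q.terms))
        lines.append("")
        result = res_by_query.get(q.query_id)
        if result:
            terms = {t for t, _ in q.terms}
            for rank, (page_id, score) in enumerate(result.ranked, start=1):
                lines.append(f"### Rank {rank}: {page_id} (BM25 {score:.2f})")
                lines.append("")
                body = pages.get(page_id, "")
                marked = " ".join(
                    f"**{w}**" if w.lower().strip(".,!?") in terms else w
                    for w in body.split()
                )
                lines.append(marked)
                lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
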