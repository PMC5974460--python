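"""Data model and I/O for annotated health-forum corpora.

A corpus is a list of conversations; each conversation is an ordered list of
posts; each post is an ordered list of sentence-type units.  Sentences carry
two kinds of annotation: a binary "has information need" (HASN) flag marking
direct or indirect requests for information, and one or two information-type
categories from a fixed ten-way taxonomy (medical, resource, social,
psychological, background, wellness, physical, previous, other, multiple).

Two annotation dialects exist.  In the ``MC`` dialect every sentence has
exactly one category and the catch-all ``multiple`` is admissible; in the
``CSN`` dialect up to two categories may be assigned and ``multiple`` is not
used.

On-disk format is JSON lines (one metadata header line, then one conversation
per line); annotations can also be overlaid from a CSV table keyed by
sentence id (``"<conversation>:<post>:<index>"``).
"""

from __future__ import annotations

import csv
import json
import math
import string
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

# --------------------------------------------------------------------------
# taxonomy

CATEGORIES: tuple[str, ...] = (
    "medical",
    "resource",
    "social",
    "psychological",
    "background",
    "wellness",
    "physical",
    "previous",
    "other",
    "multiple",
)

#: category admissible only under the MC annotation dialect
MULTIPLE = "multiple"

DIALECTS = ("MC", "CSN")


class CorpusError(ValueError):
    """Malformed corpus structure or file."""


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation overlay."""


def _check_categories(categories: Sequence[str], dialect: str, where: str) -> frozenset[str]:
    cats = frozenset(categories)
    for c in cats:
        if c not in CATEGORIES:
            raise AnnotationError(f"unknown category {c!r} at {where}")
    if not 1 <= len(cats) <= 2:
        raise AnnotationError(
            f"{where}: a sentence carries 1 or 2 categories, got {sorted(cats)}"
        )
    if len(cats) == 2 and dialect != "CSN":
        raise AnnotationError(f"{where}: two categories are only allowed in the CSN dialect")
    if MULTIPLE in cats and dialect != "MC":
        raise AnnotationError(f"{where}: category 'multiple' is only used in the MC dialect")
    return cats


# --------------------------------------------------------------------------
# segmentation and tokenization

# Abbreviations that end in a period but do not terminate a sentence.
_DEFAULT_ABBREV_PATH = Path(__file__).parent / "data" / "abbreviations.txt"
_ABBREVIATIONS: frozenset[str] | None = None


def default_abbreviations() -> frozenset[str]:
    global _ABBREVIATIONS
    if _ABBREVIATIONS is None:
        lines = _DEFAULT_ABBREV_PATH.read_text(encoding="utf-8").splitlines()
        _ABBREVIATIONS = frozenset(
            ln.strip().lower() for ln in lines if ln.strip() and not ln.startswith("#")
        )
    return _ABBREVIATIONS


_TERMINATORS = ".!?"
_TRAILERS = ".!?\"')"  # absorbed into the sentence after a boundary


def segment_post(raw_text: str, abbreviations: frozenset[str] | None = None) -> list[str]:
    """Split the raw text of one post into sentence-type units.

    Rule-based: boundaries at ``.``, ``!``, ``?`` and newlines, except that a
    period ending a known abbreviation (``dr.``, ``e.g.`` ...), following a
    single letter (initials), or inside a decimal number does not terminate
    the unit.  Runs of terminators (``...``, ``?!``) stay with the sentence.
    Whitespace around units is stripped; the concatenation of the returned
    units otherwise preserves the input.
    """
    if abbreviations is None:
        abbreviations = default_abbreviations()
    units: list[str] = []
    buf: list[str] = []
    i, n = 0, len(raw_text)
    while i < n:
        ch = raw_text[i]
        buf.append(ch)
        boundary = False
        if ch == "\n" or ch in "!?":
            boundary = True
        elif ch == ".":
            word = _trailing_word(buf)
            prev = raw_text[i - 1] if i > 0 else ""
            nxt = raw_text[i + 1] if i + 1 < n else ""
            if word.lower() in abbreviations:
                boundary = False
            elif len(word) == 2:  # single letter + period: an initial or 'e.' in 'e.g.'
                boundary = False
            elif prev.isdigit() and nxt.isdigit():
                boundary = False  # decimal number
            else:
                boundary = True
        if boundary:
            while i + 1 < n and raw_text[i + 1] in _TRAILERS:
                i += 1
                buf.append(raw_text[i])
            unit = "".join(buf).strip()
            if unit:
                units.append(unit)
            buf = []
        i += 1
    tail = "".join(buf).strip()
    if tail:
        units.append(tail)
    return units


def _trailing_word(buf: list[str]) -> str:
    j = len(buf) - 1
    while j >= 0 and not buf[j].isspace():
        j -= 1
    return "".join(buf[j + 1:])


_STRIP_CHARS = string.punctuation + "“”‘’…"


def tokenize(text: str) -> list[str]:
    """Lowercase and split on whitespace, stripping edge punctuation.

    Internal apostrophes and hyphens are kept (``don't``, ``follow-up``);
    tokens that are pure punctuation vanish.  Deterministic.
    """
    out = []
    for raw in text.lower().split():
        tok = raw.strip(_STRIP_CHARS)
        if tok:
            out.append(tok)
    return out


def bigrams(tokens: Sequence[str]) -> list[tuple[str, str]]:
    """Adjacent token pairs, in order; ``len == max(0, len(tokens) - 1)``."""
    return [(tokens[i], tokens[i + 1]) for i in range(len(tokens) - 1)]


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class Sentence:
    """One sentence-type unit with its annotations."""

    sentence_id: str
    conversation_id: str
    post_id: str
    index_in_post: int
    text: str
    categories: frozenset[str] = frozenset({"other"})
    hasn: bool = False

    @property
    def tokens(self) -> list[str]:
        return tokenize(self.text)


@dataclass(frozen=True)
class Post:
    post_id: str
    conversation_id: str
    author: str
    order: int
    sentences: tuple[Sentence, ...]

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sentences):
            if s.index_in_post != i:
                raise CorpusError(
                    f"post {self.post_id}: sentence index {s.index_in_post} at position {i}"
                )


@dataclass(frozen=True)
class Conversation:
    conversation_id: str
    posts: tuple[Post, ...]

    def sentences(self) -> Iterator[Sentence]:
        for p in self.posts:
            yield from p.sentences


@dataclass(frozen=True)
class Corpus:
    conversations: tuple[Conversation, ...]
    dialect: str = "MC"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise CorpusError(f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}")
        seen_conv: set[str] = set()
        seen_sent: set[str] = set()
        for conv in self.conversations:
            if conv.conversation_id in seen_conv:
                raise CorpusError(f"duplicate conversation id {conv.conversation_id!r}")
            seen_conv.add(conv.conversation_id)
            for s in conv.sentences():
                if s.sentence_id in seen_sent:
                    raise CorpusError(f"duplicate sentence id {s.sentence_id!r}")
                seen_sent.add(s.sentence_id)
                _check_categories(s.categories, self.dialect, s.sentence_id)

    def sentences(self) -> Iterator[Sentence]:
        for conv in self.conversations:
            yield from conv.sentences()

    def posts(self) -> Iterator[Post]:
        for conv in self.conversations:
            yield from conv.posts

    @property
    def n_sentences(self) -> int:
        return sum(1 for _ in self.sentences())

    def sentence_by_id(self) -> dict[str, Sentence]:
        return {s.sentence_id: s for s in self.sentences()}


def make_sentence_id(conversation_id: str, post_id: str, index_in_post: int) -> str:
    return f"{conversation_id}:{post_id}:{index_in_post}"


# --------------------------------------------------------------------------
# descriptive statistics

@dataclass(frozen=True)
class DescriptiveStats:
    n_conversations: int
    n_posts: int
    n_sentences: int
    mean_sentences_per_post: float
    sd_sentences_per_post: float
    mean_words_per_sentence: float
    sd_words_per_sentence: float
    mean_chars_per_word: float
    sd_chars_per_word: float
    hasn_fraction: float
    category_fractions: Mapping[str, float]


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    # sample SD (n-1 denominator); 0.0 when fewer than two observations
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def corpus_stats(corpus: Corpus) -> DescriptiveStats:
    """Descriptive statistics over a corpus.

    Means and SDs use the sample (n-1) convention.  Each sentence contributes
    one count to each of its categories with n_sentences as the denominator,
    so under the two-label CSN dialect the category fractions may sum to more
    than 1.
    """
    sent_per_post = [len(p.sentences) for p in corpus.posts()]
    all_sentences = list(corpus.sentences())
    if not all_sentences:
        raise CorpusError("corpus contains no sentences")
    words_per_sentence = [len(s.tokens) for s in all_sentences]
    word_lengths = [len(t) for s in all_sentences for t in s.tokens]
    n_sent = len(all_sentences)
    cat_counts = {c: 0 for c in CATEGORIES}
    n_hasn = 0
    for s in all_sentences:
        if s.hasn:
            n_hasn += 1
        for c in s.categories:
            cat_counts[c] += 1
    m_spp, sd_spp = _mean_sd(sent_per_post)
    m_wps, sd_wps = _mean_sd(words_per_sentence)
    m_cpw, sd_cpw = _mean_sd(word_lengths) if word_lengths else (0.0, 0.0)
    return DescriptiveStats(
        n_conversations=len(corpus.conversations),
        n_posts=len(sent_per_post),
        n_sentences=n_sent,
        mean_sentences_per_post=m_spp,
        sd_sentences_per_post=sd_spp,
        mean_words_per_sentence=m_wps,
        sd_words_per_sentence=sd_wps,
        mean_chars_per_word=m_cpw,
        sd_chars_per_word=sd_cpw,
        hasn_fraction=n_hasn / n_sent,
        category_fractions={c: cat_counts[c] / n_sent for c in CATEGORIES},
    )


# --------------------------------------------------------------------------
# file I/O

def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write JSONL: one metadata header line, then one conversation per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = {"record": "meta", "dialect": corpus.dialect, "provenance": corpus.provenance}
        fh.write(json.dumps(header, ensure_ascii=False) + "\n")
        for conv in corpus.conversations:
            rec = {
                "record": "conversation",
                "conversation_id": conv.conversation_id,
                "posts": [
                    {
                        "post_id": p.post_id,
                        "author": p.author,
                        "order": p.order,
                        "sentences": [
                            {
                                "text": s.text,
                                "categories": sorted(s.categories),
                                "hasn": s.hasn,
                            }
                            for s in p.sentences
                        ],
                    }
                    for p in conv.posts
                ],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSONL corpus file; errors name the offending line number."""
    path = Path(path)
    conversations: list[Conversation] = []
    dialect = "MC"
    provenance = ""
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            kind = rec.get("record")
            if kind == "meta":
                dialect = rec.get("dialect", "MC")
                provenance = rec.get("provenance", "")
            elif kind == "conversation":
                try:
                    conversations.append(_parse_conversation(rec))
                except (KeyError, TypeError, CorpusError, AnnotationError) as exc:
                    raise CorpusError(f"{path}:{lineno}: {exc}") from exc
            else:
                raise CorpusError(f"{path}:{lineno}: unknown record type {kind!r}")
    return Corpus(tuple(conversations), dialect=dialect, provenance=provenance)


def _parse_conversation(rec: Mapping) -> Conversation:
    cid = rec["conversation_id"]
    posts = []
    for p in rec["posts"]:
        pid = p["post_id"]
        sentences = tuple(
            Sentence(
                sentence_id=make_sentence_id(cid, pid, i),
                conversation_id=cid,
                post_id=pid,
                index_in_post=i,
                text=s["text"],
                categories=frozenset(s["categories"]),
                hasn=bool(s["hasn"]),
            )
            for i, s in enumerate(p["sentences"])
        )
        posts.append(
            Post(post_id=pid, conversation_id=cid, author=p.get("author", ""),
                 order=p.get("order", len(posts)), sentences=sentences)
        )
    return Conversation(conversation_id=cid, posts=tuple(posts))


ANNOTATION_HEADER = ["sentence_id", "hasn", "category1", "category2"]


def read_annotations(path: str | Path) -> dict[str, tuple[bool, frozenset[str]]]:
    """Read an annotation overlay CSV keyed by sentence_id.

    Columns: ``sentence_id,hasn,category1,category2`` (category2 may be
    empty).  Category names are validated against the closed taxonomy; errors
    name the line number and the offending name.
    """
    path = Path(path)
    overlay: dict[str, tuple[bool, frozenset[str]]] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ANNOTATION_HEADER:
            raise AnnotationError(
                f"{path}: expected header {ANNOTATION_HEADER}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            sid = row["sentence_id"]
            cats = [c for c in (row["category1"], row["category2"]) if c]
            for c in cats:
                if c not in CATEGORIES:
                    raise AnnotationError(f"{path}:{lineno}: unknown category {c!r}")
            hasn_raw = row["hasn"].strip().lower()
            if hasn_raw not in {"0", "1", "true", "false"}:
                raise AnnotationError(f"{path}:{lineno}: bad hasn value {row['hasn']!r}")
            overlay[sid] = (hasn_raw in {"1", "true"}, frozenset(cats))
    return overlay


def write_annotations(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_HEADER)
        for s in corpus.sentences():
            cats = sorted(s.categories)
            writer.writerow([s.sentence_id, int(s.hasn), cats[0], cats[1] if len(cats) > 1 else ""])


def apply_annotations(
    corpus: Corpus, overlay: Mapping[str, tuple[bool, frozenset[str]]]
) -> Corpus:
    """Join an overlay onto a corpus by sentence_id; unknown ids are rejected."""
    known = {s.sentence_id for s in corpus.sentences()}
    unknown = sorted(set(overlay) - known)
    if unknown:
        raise AnnotationError(f"annotation rows reference unknown sentence ids: {unknown[:5]}")
    new_convs = []
    for conv in corpus.conversations:
        new_posts = []
        for p in conv.posts:
            new_sents = []
            for s in p.sentences:
                if s.sentence_id in overlay:
                    hasn, cats = overlay[s.sentence_id]
                    s = replace(s, hasn=hasn, categories=cats)
                new_sents.append(s)
            new_posts.append(replace(p, sentences=tuple(new_sents)))
        new_convs.append(replace(conv, posts=tuple(new_posts)))
    return Corpus(tuple(new_convs), dialect=corpus.dialect, provenance=corpus.provenance)


def write_report(stats: DescriptiveStats, path: str | Path) -> None:
    """Write a stats report: CSV at ``path`` plus a human-readable ``.txt`` sibling."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["statistic", "value"])
        writer.writerow(["n_conversations", stats.n_conversations])
        writer.writerow(["n_posts", stats.n_posts])
        writer.writerow(["n_sentences", stats.n_sentences])
        writer.writerow(["mean_sentences_per_post", f"{stats.mean_sentences_per_post:.4f}"])
        writer.writerow(["sd_sentences_per_post", f"{stats.sd_sentences_per_post:.4f}"])
        writer.writerow(["mean_words_per_sentence", f"{stats.mean_words_per_sentence:.4f}"])
        writer.writerow(["sd_words_per_sentence", f"{stats.sd_words_per_sentence:.4f}"])
        writer.writerow(["mean_chars_per_word", f"{stats.mean_chars_per_word:.4f}"])
        writer.writerow(["sd_chars_per_word", f"{stats.sd_chars_per_word:.4f}"])
        writer.writerow(["hasn_fraction", f"{stats.hasn_fraction:.4f}"])
        for c in CATEGORIES:
            writer.writerow([f"fraction_{c}", f"{stats.category_fractions[c]:.4f}"])
    path.with_suffix(".txt").write_text(format_report(stats), encoding="utf-8")


def format_report(stats: DescriptiveStats) -> str:
    lines = [
        f"Conversations: {stats.n_conversations}",
        f"Posts: {stats.n_posts}",
        f"Sentences: {stats.n_sentences}",
        f"Sentences per post: {stats.mean_sentences_per_post:.2f} (SD {stats.sd_sentences_per_post:.2f})",
        f"Words per sentence: {stats.mean_words_per_sentence:.2f} (SD {stats.sd_words_per_sentence:.2f})",
        f"Characters per word: {stats.mean_chars_per_word:.2f} (SD {stats.sd_chars_per_word:.2f})",
        f"Sentences expressing an information need: {100 * stats.hasn_fraction:.1f}%",
        "Category fractions:",
    ]
    for c in CATEGORIES:
        lines.append(f"  {c:>13s}: {100 * stats.category_fractions[c]:.1f}%")
    return "\n".join(lines) + "\n"
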