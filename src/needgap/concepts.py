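"""Frequency-ranked concept profiling per information category.

Concept tagging is a pluggable lexicon lookup: lowercased surface terms of
one to three tokens map to concept names, matched greedily left-to-right
with longest-match precedence and no overlaps.  A compact breast-cancer
lexicon is packaged as the default; any term,concept CSV (for example one
derived from a licensed medical thesaurus) can be substituted.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import CATEGORIES, Corpus, Sentence, tokenize

_DEFAULT_LEXICON_PATH = Path(__file__).parent / "data" / "concept_lexicon.csv"

MAX_TERM_TOKENS = 3


@dataclass(frozen=True)
class ConceptLexicon:
    """Mapping from lowercased surface term (1-3 tokens) to concept name."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for term in self.entries:
            if not term.strip():
                raise ValueError("empty surface term in lexicon")
            n = len(term.split())
            if not 1 <= n <= MAX_TERM_TOKENS:
                raise ValueError(f"term {term!r} has {n} tokens; allowed 1-{MAX_TERM_TOKENS}")

    @classmethod
    def from_file(cls, path: str | Path) -> "ConceptLexicon":
        entries: dict[str, str] = {}
        with Path(path).open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != ["term", "concept"]:
                raise ValueError(f"{path}: expected header term,concept")
            for row in reader:
                entries[row["term"].strip().lower()] = row["concept"].strip()
        return cls(entries)


def default_lexicon() -> ConceptLexicon:
    return ConceptLexicon.from_file(_DEFAULT_LEXICON_PATH)


def tag_concepts(sentence: Sentence | Sequence[str] | str,
                 lexicon: ConceptLexicon) -> Counter:
    """Concept multiset for one sentence.

    Greedy longest-match left-to-right over the token stream: at each
    position the longest matching term (up to 3 tokens) wins and the scan
    resumes after it, so matches never overlap.
    """
    if isinstance(sentence, Sentence):
        tokens = sentence.tokens
    elif isinstance(sentence, str):
        tokens = tokenize(sentence)
    else:
        tokens = list(sentence)
    found: Counter = Counter()
    i = 0
    while i < len(tokens):
        matched = False
        for length in range(min(MAX_TERM_TOKENS, len(tokens) - i), 0, -1):
            term = " ".join(tokens[i:i + length])
            concept = lexicon.entries.get(term)
            if concept is not None:
                found[concept] += 1
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return found


def rank_concepts(corpus: Corpus, category: str,
                  lexicon: ConceptLexicon | None = None,
                  k: int = 5) -> list[tuple[str, int]]:
    """Top-k concepts, by count, over sentences carrying ``category``.

    Counts are summed over all sentences labelled with the category; ties
    break alphabetically, making the ranking deterministic.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if lexicon is None:
        lexicon = default_lexicon()
    totals: Counter = Counter()
    for s in corpus.sentences():
        if category in s.categories:
            totals.update(tag_concepts(s, lexicon))
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def write_concept_table(corpus: Corpus, path: str | Path,
                        lexicon: ConceptLexicon | None = None, k: int = 5) -> None:
    """CSV of (category, rank, concept, count) for every category present."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", "rank", "concept", "count"])
        for category in CATEGORIES:
            if not any(category in s.categories for s in corpus.sentences()):
                continue
            for rank, (concept, count) in enumerate(
                    rank_concepts(corpus, category, lexicon, k), start=1):
                writer.writerow([category, rank, concept, count])
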