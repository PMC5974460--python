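"""Rule-based information-need detection via induced bigram patterns.

A cue vocabulary V holds potential question cues: wh-words, auxiliary verbs,
pronouns, and words associated with direct or indirect requests
("wondering", "advice", "anyone", ...).  For each positive training sentence
not yet matched by an accepted pattern, induction searches for the smallest
set of that sentence's adjacent V-bigrams such that no negative training
sentence contains every bigram in the set; the first such set (by increasing
cardinality, then left-to-right sentence position) becomes a pattern.
Positives for which no separating set exists up to the cardinality cap are
recorded as unseparable.

A sentence matches a ruleset when some pattern's bigrams all occur among the
sentence's adjacent token pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

from .corpus import Sentence, bigrams, tokenize

_DEFAULT_VOCAB_PATH = Path(__file__).parent / "data" / "cue_vocab.txt"

#: patterns larger than this overfit single training sentences
MAX_PATTERN_SIZE = 4

Bigram = tuple[str, str]


@dataclass(frozen=True)
class CueVocabulary:
    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError("cue vocabulary is empty")

    def __contains__(self, word: str) -> bool:
        return word in self.words

    @classmethod
    def from_file(cls, path: str | Path) -> "CueVocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls(frozenset(
            ln.strip().lower() for ln in lines if ln.strip() and not ln.startswith("#")
        ))


def default_cue_vocabulary() -> CueVocabulary:
    return CueVocabulary.from_file(_DEFAULT_VOCAB_PATH)


@dataclass(frozen=True)
class BigramPattern:
    bigram_set: frozenset[Bigram]
    source_example_id: str
    #: number of training positives this pattern matched during induction
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not self.bigram_set:
            raise ValueError("pattern needs at least one bigram")


@dataclass(frozen=True)
class Ruleset:
    patterns: tuple[BigramPattern, ...]
    unseparable: tuple[str, ...] = ()


def _tokens_of(sentence: Sentence | Sequence[str] | str) -> list[str]:
    if isinstance(sentence, Sentence):
        return sentence.tokens
    if isinstance(sentence, str):
        return tokenize(sentence)
    return list(sentence)


def candidate_bigrams(sentence: Sentence | Sequence[str] | str,
                      vocabulary: CueVocabulary) -> list[Bigram]:
    """Adjacent token pairs with both members in V, ordered by first
    occurrence in the sentence (duplicates collapsed)."""
    seen: dict[Bigram, None] = {}
    for a, b in bigrams(_tokens_of(sentence)):
        if a in vocabulary and b in vocabulary:
            seen.setdefault((a, b))
    return list(seen)


def _id_of(sentence, fallback: str) -> str:
    return sentence.sentence_id if isinstance(sentence, Sentence) else fallback


def induce_patterns(positives: Sequence, negatives: Sequence,
                    vocabulary: CueVocabulary | None = None,
                    max_size: int = MAX_PATTERN_SIZE) -> Ruleset:
    """Induce a minimal separating bigram pattern per unmatched positive.

    Positives are processed in input (corpus) order.  A positive already
    matched by an accepted pattern is skipped (the pattern's multiplicity is
    incremented).  Candidate subsets are searched by increasing cardinality
    and, within one cardinality, lexicographically over the bigrams sorted by
    sentence position; the search is capped at ``max_size`` bigrams, beyond
    which the positive is recorded as unseparable.  By construction no
    accepted pattern matches any negative.
    """
    if vocabulary is None:
        vocabulary = default_cue_vocabulary()
    negative_pairs = [frozenset(bigrams(_tokens_of(n))) for n in negatives]
    patterns: list[BigramPattern] = []
    counts: list[int] = []
    unseparable: list[str] = []
    for i, pos in enumerate(positives):
        pos_pairs = frozenset(bigrams(_tokens_of(pos)))
        matched = False
        for j, pat in enumerate(patterns):
            if pat.bigram_set <= pos_pairs:
                counts[j] += 1
                matched = True
                break
        if matched:
            continue
        cands = candidate_bigrams(pos, vocabulary)
        found: frozenset[Bigram] | None = None
        for size in range(1, min(max_size, len(cands)) + 1):
            for combo in combinations(cands, size):
                s = frozenset(combo)
                if not any(s <= neg for neg in negative_pairs):
                    found = s
                    break
            if found is not None:
                break
        if found is None:
            unseparable.append(_id_of(pos, f"positive:{i}"))
        else:
            patterns.append(BigramPattern(found, _id_of(pos, f"positive:{i}")))
            counts.append(1)
    final = tuple(
        BigramPattern(p.bigram_set, p.source_example_id, multiplicity=c)
        for p, c in zip(patterns, counts)
    )
    return Ruleset(final, tuple(unseparable))


def match(ruleset: Ruleset, sentence: Sentence | Sequence[str] | str) -> bool:
    """True iff some pattern's bigrams all occur adjacently in the sentence."""
    pairs = frozenset(bigrams(_tokens_of(sentence)))
    return any(p.bigram_set <= pairs for p in ruleset.patterns)


# --------------------------------------------------------------------------
# binary evaluation

@dataclass(frozen=True)
class BinaryMetrics:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    #: set when a zero denominator forced the metric to 0
    warnings: tuple[str, ...] = ()


def evaluate_binary(predicted: Sequence[bool], gold: Sequence[bool]) -> BinaryMetrics:
    """Positive-class precision, recall and F = 2PR/(P+R).

    A zero denominator (no predicted positives, no gold positives, or
    P = R = 0) yields 0 for the affected metric together with a warning flag.
    """
    if len(predicted) != len(gold):
        raise ValueError(f"length mismatch: {len(predicted)} predictions, {len(gold)} gold")
    tp = sum(1 for p, g in zip(predicted, gold) if p and g)
    fp = sum(1 for p, g in zip(predicted, gold) if p and not g)
    fn = sum(1 for p, g in zip(predicted, gold) if not p and g)
    tn = len(gold) - tp - fp - fn
    warnings = []
    if tp + fp == 0:
        precision, w = 0.0, "no predicted positives"
        warnings.append(w)
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        warnings.append("no gold positives")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        warnings.append("F undefined (P + R = 0)")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return BinaryMetrics(precision, recall, f1, tp, fp, fn, tn, tuple(warnings))


# --------------------------------------------------------------------------
# serialization

def write_ruleset(ruleset: Ruleset, path: str | Path) -> None:
    payload = {
        "patterns": [
            {
                "bigrams": [list(bg) for bg in sorted(p.bigram_set)],
                "source_example_id": p.source_example_id,
                "multiplicity": p.multiplicity,
            }
            for p in ruleset.patterns
        ],
        "unseparable": list(ruleset.unseparable),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_ruleset(path: str | Path) -> Ruleset:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    patterns = tuple(
        BigramPattern(
            frozenset(tuple(bg) for bg in rec["bigrams"]),
            rec["source_example_id"],
            rec.get("multiplicity", 1),
        )
        for rec in payload["patterns"]
    )
    return Ruleset(patterns, tuple(payload.get("unseparable", ())))
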