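"""Synthetic forum corpora, education pages, and simulated relevance raters.

Real peer-support forum data cannot be redistributed, so this module
generates labelled stand-ins that reproduce the statistical structure the
rest of the pipeline assumes: truncated-normal post/sentence/word length
profiles, a configurable category mixture with per-category information-need
(HASN) rates, referential ("previous") sentences that restate a preceding
need without topical content, and a patient-education page collection whose
fraction of covered need topics is a dial.

Sentences are template realizations over per-category vocabulary banks with
category-exclusive content words plus shared filler words.  A HASN sentence
is realized either as a wh-question or as an indirect statement ("i was
wondering about ...") in equal proportion, matching the definition of an
information need as covering both direct and implicit questions.

One integer seed drives three independent sub-streams (corpus, pages,
raters) so each generator can be re-run on its own and still reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import (
    CATEGORIES,
    Conversation,
    Corpus,
    Post,
    Sentence,
    make_sentence_id,
)

# --------------------------------------------------------------------------
# vocabulary banks

#: Category-exclusive content words.  Disjoint from FILLER_WORDS and from
#: each other, so a category's words identify it unambiguously.
DEFAULT_VOCAB_BANKS: dict[str, tuple[str, ...]] = {
    "medical": ("chemo", "radiation", "taxol", "mastectomy", "lumpectomy",
                "biopsy", "tumor", "oncologist", "herceptin", "tamoxifen",
                "reconstruction", "mammogram"),
    "physical": ("pain", "sore", "tired", "swelling", "nausea", "numbness",
                 "hair", "itching", "headache", "lymphedema"),
    "psychological": ("scared", "anxiety", "depressed", "fear", "crying",
                      "worry", "stress", "sadness", "mood", "panic"),
    "background": ("husband", "daughter", "retired", "teacher", "family",
                   "grandchildren", "married", "job", "sister", "mother"),
    "wellness": ("exercise", "diet", "vitamins", "yoga", "walking",
                 "nutrition", "sleep", "hydration", "meditation", "shampoo"),
    "resource": ("website", "brochure", "book", "pamphlet", "hotline",
                 "library", "article", "blog", "podcast", "booklet"),
    "social": ("hugs", "congratulations", "welcome", "blessings", "prayers",
               "greetings", "luck", "wishes", "cheers", "kindness"),
    "other": ("insurance", "travel", "wig", "prosthesis", "finances",
              "paperwork", "appointment", "parking", "pharmacy", "billing"),
}

#: Shared filler words, common to every category (and thus uninformative).
FILLER_WORDS: tuple[str, ...] = (
    "today", "morning", "week", "month", "year", "going", "feeling", "little",
    "thing", "things", "started", "think", "made", "good", "long", "last",
    "next", "home", "time", "still", "just", "been", "very", "quite", "some",
    "most", "every", "again", "since", "about", "after", "before", "while",
    "really", "pretty", "kind", "sort", "day", "days", "then",
)

_DIRECT_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("how", "do", "i", "deal", "with"),
    ("what", "can", "i", "do", "about"),
    ("does", "anyone", "know", "about"),
    ("where", "can", "i", "find"),
    ("how", "long", "does"),
)
_INDIRECT_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("i", "was", "wondering", "about"),
    ("i", "am", "concerned", "about"),
    # subject-dropped phrasing common in forum posts; contains no adjacent
    # cue-vocabulary pair, so it is invisible to bigram patterns over V
    ("curious", "whether", "anybody", "tried"),
    ("i", "was", "wanting", "advice", "on"),
)
# "previous" sentences: a referring cue (this/that/it) and no content word.
_PREVIOUS_HASN_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("anyone", "else", "have", "this"),
    ("any", "answers", "out", "there", "about", "that"),
    ("did", "anyone", "else", "experience", "it"),
    ("is", "this", "normal"),
)
_PREVIOUS_PLAIN_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("that", "was", "how", "it", "went", "for", "me"),
    ("this", "helped", "me", "a", "lot"),
    ("it", "was", "the", "same", "for", "me"),
)


def substream(seed: int, key: int) -> np.random.Generator:
    """Independent generator number ``key`` derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class LengthDistribution:
    """Rounded normal truncated below at ``minimum``."""

    mean: float
    sd: float
    minimum: int = 1

    def draw(self, rng: np.random.Generator) -> int:
        return max(self.minimum, round(rng.normal(self.mean, self.sd)))


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_conversations: int = 65
    #: when set, generation stops at exactly this many sentences instead of
    #: at n_conversations (overshoot in the last post is trimmed)
    n_sentences: int | None = None
    posts_per_conversation: LengthDistribution = LengthDistribution(4.7, 2.5)
    sentences_per_post: LengthDistribution = LengthDistribution(6.35, 4.42)
    words_per_sentence: LengthDistribution = LengthDistribution(14.04, 6.30)
    category_mixture: Mapping[str, float] = field(default_factory=dict)
    hasn_rate_by_category: Mapping[str, float] = field(default_factory=dict)
    previous_follow_rate: float = 0.0
    #: probability the next sentence repeats the previous one's category
    #: (label autocorrelation; 0 = independent draws)
    category_stickiness: float = 0.0
    #: probability a content-word slot is filled from a random other bank
    vocab_noise: float = 0.0
    #: CSN only: probability of attaching a second category label
    second_label_rate: float = 0.0
    dialect: str = "MC"
    vocab_banks: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_VOCAB_BANKS)
    )

    def validate(self) -> None:
        if not self.category_mixture:
            raise ValueError("category_mixture is empty")
        total = sum(self.category_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mixture sums to {total}, expected 1")
        for name, p in [("previous_follow_rate", self.previous_follow_rate),
                        ("category_stickiness", self.category_stickiness),
                        ("vocab_noise", self.vocab_noise),
                        ("second_label_rate", self.second_label_rate)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for c, p in {**self.category_mixture, **self.hasn_rate_by_category}.items():
            if c not in CATEGORIES:
                raise ValueError(f"unknown category {c!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {c!r} out of [0, 1]: {p}")


# MayoConnect profile: 65 conversations / 1943 sentences; per-category counts
# from the published distribution table (they sum to 1942; normalized here).
_MC_COUNTS = {
    "medical": 597, "resource": 87, "social": 353, "psychological": 61,
    "background": 69, "wellness": 88, "physical": 167, "previous": 147,
    "other": 313, "multiple": 60,
}
_MC_HASN = {
    "medical": 34 / 597, "resource": 9 / 87, "wellness": 3 / 88,
    "physical": 18 / 167, "other": 8 / 313,
    # mixture-drawn rate; restatements inserted after need sentences
    # (previous_follow_rate) supply the remainder of the "previous" needs
    "previous": 0.16,
}

# Cancer Survivors Network profile: label counts sum to 2473 over 2246
# sentences because up to two labels were allowed; the normalized counts act
# as the primary-label mixture and second labels are attached at ~10%.
_CSN_COUNTS = {
    "medical": 473, "resource": 32, "social": 443, "psychological": 63,
    "background": 38, "wellness": 78, "physical": 193, "previous": 425,
    "other": 728,
}
_CSN_HASN = {
    "medical": 48 / 473, "resource": 9 / 32, "social": 9 / 443,
    "psychological": 5 / 63, "wellness": 5 / 78, "physical": 15 / 193,
    "other": 24 / 728, "previous": 0.10,
}


def _normalize(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    mix = {c: n / total for c, n in counts.items()}
    # nudge the largest entry so the mixture sums to exactly 1.0
    drift = 1.0 - sum(mix.values())
    top = max(mix, key=mix.get)
    mix[top] += drift
    return mix


def mc_profile(seed: int = 0, n_conversations: int = 65,
               n_sentences: int | None = None) -> GeneratorConfig:
    """Generator configuration matching the MayoConnect descriptive profile."""
    return GeneratorConfig(
        seed=seed,
        n_conversations=n_conversations,
        n_sentences=n_sentences,
        posts_per_conversation=LengthDistribution(4.7, 2.5),
        sentences_per_post=LengthDistribution(6.35, 4.42),
        words_per_sentence=LengthDistribution(14.04, 6.30),
        category_mixture=_normalize(_MC_COUNTS),
        hasn_rate_by_category=dict(_MC_HASN),
        previous_follow_rate=0.15,
        dialect="MC",
    )


def csn_profile(seed: int = 0, n_conversations: int = 195,
                n_sentences: int | None = None) -> GeneratorConfig:
    """Generator configuration matching the Cancer Survivors Network profile."""
    return GeneratorConfig(
        seed=seed,
        n_conversations=n_conversations,
        n_sentences=n_sentences,
        posts_per_conversation=LengthDistribution(1.7, 0.9),
        sentences_per_post=LengthDistribution(11.52, 5.29),
        words_per_sentence=LengthDistribution(13.97, 5.30),
        category_mixture=_normalize(_CSN_COUNTS),
        hasn_rate_by_category=dict(_CSN_HASN),
        previous_follow_rate=0.25,
        second_label_rate=0.10,
        dialect="CSN",
    )


# --------------------------------------------------------------------------
# corpus generation

def _realize(rng: np.random.Generator, config: GeneratorConfig,
             categories: frozenset[str], hasn: bool, n_words: int) -> str:
    """Render a sentence of exactly ``n_words`` whitespace tokens."""
    banks = config.vocab_banks
    is_previous = "previous" in categories
    if hasn:
        if is_previous:
            templates = _PREVIOUS_HASN_TEMPLATES
            prefix = list(templates[rng.integers(len(templates))])
        elif rng.random() < 0.5:
            prefix = list(_DIRECT_TEMPLATES[rng.integers(len(_DIRECT_TEMPLATES))])
        else:
            prefix = list(_INDIRECT_TEMPLATES[rng.integers(len(_INDIRECT_TEMPLATES))])
    elif is_previous:
        prefix = list(_PREVIOUS_PLAIN_TEMPLATES[rng.integers(len(_PREVIOUS_PLAIN_TEMPLATES))])
    else:
        prefix = []

    if len(prefix) >= n_words:
        words = prefix[:n_words]
        if is_previous and not set(words) & {"this", "that", "it"}:
            words[-1] = "this"  # keep the referring cue under truncation
    else:
        remaining = n_words - len(prefix)
        content: list[str] = []
        if not is_previous:
            source_cats = [c for c in sorted(categories) if c in banks]
            if "multiple" in categories and not source_cats:
                bank_names = sorted(banks)
                picks = rng.choice(len(bank_names), size=2, replace=False)
                source_cats = [bank_names[i] for i in picks]
            if source_cats:
                n_content = int(min(remaining, 1 + rng.integers(0, 3)))
                for _ in range(n_content):
                    cat = source_cats[rng.integers(len(source_cats))]
                    bank = banks[cat]
                    if config.vocab_noise > 0 and rng.random() < config.vocab_noise:
                        other = sorted(set(banks) - {cat})
                        bank = banks[other[rng.integers(len(other))]]
                    content.append(bank[rng.integers(len(bank))])
        n_fill = remaining - len(content)
        fillers = [FILLER_WORDS[rng.integers(len(FILLER_WORDS))] for _ in range(n_fill)]
        body = content + fillers
        rng.shuffle(body)
        words = prefix + body
    text = " ".join(words)
    text = text[0].upper() + text[1:] if text else text
    return text + ("?" if hasn else ".")


def _draw_labels(rng: np.random.Generator, config: GeneratorConfig,
                 cats: list[str], probs: np.ndarray,
                 prev_cat: str | None) -> tuple[str, frozenset[str]]:
    if prev_cat is not None and config.category_stickiness > 0 and \
            rng.random() < config.category_stickiness:
        primary = prev_cat
    else:
        primary = cats[rng.choice(len(cats), p=probs)]
    labels = {primary}
    if config.dialect == "CSN" and config.second_label_rate > 0 and \
            rng.random() < config.second_label_rate:
        others = [c for c in cats if c != primary]
        if others:
            labels.add(others[rng.integers(len(others))])
    return primary, frozenset(labels)


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a labelled corpus; same config (incl. seed) -> identical corpus."""
    config.validate()
    rng = substream(config.seed, 0)
    cats = [c for c in CATEGORIES if config.category_mixture.get(c, 0.0) > 0]
    probs = np.array([config.category_mixture[c] for c in cats], dtype=float)
    probs = probs / probs.sum()

    conversations: list[Conversation] = []
    total = 0
    conv_idx = 0
    while True:
        if config.n_sentences is not None:
            if total >= config.n_sentences:
                break
        elif conv_idx >= config.n_conversations:
            break
        cid = f"c{conv_idx:04d}"
        n_posts = config.posts_per_conversation.draw(rng)
        posts: list[Post] = []
        for p_idx in range(n_posts):
            pid = f"p{p_idx:03d}"
            n_sent = config.sentences_per_post.draw(rng)
            sentences: list[Sentence] = []
            prev_cat: str | None = None
            for _ in range(n_sent):
                primary, labels = _draw_labels(rng, config, cats, probs, prev_cat)
                prev_cat = primary
                hasn = rng.random() < config.hasn_rate_by_category.get(primary, 0.0)
                n_words = config.words_per_sentence.draw(rng)
                text = _realize(rng, config, labels, hasn, n_words)
                idx = len(sentences)
                sentences.append(Sentence(
                    sentence_id=make_sentence_id(cid, pid, idx),
                    conversation_id=cid, post_id=pid, index_in_post=idx,
                    text=text, categories=labels, hasn=hasn,
                ))
                if hasn and "previous" not in labels and \
                        rng.random() < config.previous_follow_rate:
                    # referential restatement of the need just expressed
                    n_words2 = config.words_per_sentence.draw(rng)
                    text2 = _realize(rng, config, frozenset({"previous"}), True, n_words2)
                    idx2 = len(sentences)
                    sentences.append(Sentence(
                        sentence_id=make_sentence_id(cid, pid, idx2),
                        conversation_id=cid, post_id=pid, index_in_post=idx2,
                        text=text2, categories=frozenset({"previous"}), hasn=True,
                    ))
            author = f"user{(conv_idx + p_idx) % 7:02d}"
            posts.append(Post(post_id=pid, conversation_id=cid, author=author,
                              order=p_idx, sentences=tuple(sentences)))
            total += len(sentences)
        conversations.append(Conversation(conversation_id=cid, posts=tuple(posts)))
        conv_idx += 1

    if config.n_sentences is not None and total > config.n_sentences:
        conversations = _trim(conversations, total - config.n_sentences)
    return Corpus(tuple(conversations), dialect=config.dialect,
                  provenance=f"synthetic seed={config.seed}")


def _trim(conversations: list[Conversation], excess: int) -> list[Conversation]:
    """Drop ``excess`` sentences from the tail, removing emptied posts."""
    out = list(conversations)
    while excess > 0 and out:
        conv = out[-1]
        posts = list(conv.posts)
        last = posts[-1]
        drop = min(excess, len(last.sentences))
        kept = last.sentences[: len(last.sentences) - drop]
        excess -= drop
        if kept:
            posts[-1] = Post(post_id=last.post_id, conversation_id=last.conversation_id,
                             author=last.author, order=last.order, sentences=kept)
        else:
            posts.pop()
        if posts:
            out[-1] = Conversation(conversation_id=conv.conversation_id, posts=tuple(posts))
        else:
            out.pop()
    return out


# --------------------------------------------------------------------------
# education pages

@dataclass(frozen=True)
class EducationConfig:
    seed: int = 0
    n_pages: int = 30
    words_per_page: int = 150
    #: fraction of need topics planted in at least one page
    coverage_fraction: float = 1.0


def education_topics(config: GeneratorConfig) -> list[str]:
    """Need topics a page collection can cover: banked categories that carry
    topical content (social pleasantries and referential sentences do not)."""
    return sorted(c for c in config.vocab_banks if c not in ("social", "previous"))


def generate_education_pages(
    econfig: EducationConfig,
    gconfig: GeneratorConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Generate education pages plus the gold topic->pages coverage map.

    Exactly ``round(coverage_fraction * n_topics)`` topics receive at least
    one page containing >= 3 of their exclusive words; the words of every
    other topic appear in no page.
    """
    if not 0.0 <= econfig.coverage_fraction <= 1.0:
        raise ValueError(f"coverage_fraction must be in [0, 1], got {econfig.coverage_fraction}")
    rng = substream(econfig.seed, 1)
    topics = education_topics(gconfig)
    n_covered = round(econfig.coverage_fraction * len(topics))
    if n_covered > econfig.n_pages:
        raise ValueError(f"{n_covered} covered topics need at least that many pages, "
                         f"got n_pages={econfig.n_pages}")
    picks = rng.choice(len(topics), size=n_covered, replace=False)
    covered = sorted(topics[i] for i in picks)

    pages: list[tuple[str, str]] = []
    gold: dict[str, list[str]] = {t: [] for t in covered}
    # each covered topic gets a block of pages; remaining pages are filler-only
    pages_per_topic = max(1, econfig.n_pages // (2 * n_covered)) if n_covered else 0
    for j in range(econfig.n_pages):
        page_id = f"page{j:03d}"
        topic: str | None = None
        if n_covered and j < n_covered * pages_per_topic:
            topic = covered[j // pages_per_topic]
        words = [FILLER_WORDS[rng.integers(len(FILLER_WORDS))]
                 for _ in range(econfig.words_per_page)]
        if topic is not None:
            # a covering page mentions most of its topic's vocabulary, so the
            # topic is findable through any of its characteristic terms
            bank = list(gconfig.vocab_banks[topic])
            n_plant = int(rng.integers(max(3, (2 * len(bank)) // 3), len(bank) + 1))
            plant_idx = rng.choice(len(bank), size=n_plant, replace=False)
            planted = [bank[i] for i in plant_idx]
            positions = rng.choice(len(words), size=n_plant, replace=False)
            for pos, w in zip(sorted(positions), planted):
                words[pos] = w
            gold[topic].append(page_id)
        text = " ".join(words) + "\n"
        pages.append((page_id, text))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for page_id, text in pages:
            (out_dir / f"{page_id}.txt").write_text(text, encoding="utf-8")
    return pages, gold


def write_gold_coverage(gold: Mapping[str, Sequence[str]], path: str | Path) -> None:
    import csv

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["topic", "page_ids"])
        for topic in sorted(gold):
            writer.writerow([topic, "|".join(gold[topic])])


def read_gold_coverage(path: str | Path) -> dict[str, list[str]]:
    import csv

    gold: dict[str, list[str]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            gold[row["topic"]] = [p for p in row["page_ids"].split("|") if p]
    return gold


# --------------------------------------------------------------------------
# simulated raters

@dataclass(frozen=True)
class RaterConfig:
    seed: int = 0
    n_raters: int = 2
    #: probability a rater marks a truly covering page as relevant
    sensitivity: float = 1.0
    false_positive_rate: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity out of [0, 1]: {self.sensitivity}")
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ValueError(f"false_positive_rate out of [0, 1]: {self.false_positive_rate}")
        if self.n_raters < 1:
            raise ValueError("need at least one rater")


def simulate_raters(results, gold_coverage: Mapping[str, Sequence[str]],
                    config: RaterConfig, query_topics: Mapping[str, str]):
    """Draw independent per-rater relevance verdicts for retrieved pages.

    A page truly satisfies a query when it appears in ``gold_coverage`` under
    the query's gold topic (``query_topics``); the rater then marks it
    relevant with probability ``sensitivity``, otherwise with probability
    ``false_positive_rate``.
    """
    from .gap import RatingRow, RatingTable

    config.validate()
    rng = substream(config.seed, 2)
    covering = {t: set(pages) for t, pages in gold_coverage.items()}
    rows: list[RatingRow] = []
    for result in results:
        topic = query_topics.get(result.query_id)
        for page_id, _score in result.ranked:
            truly = topic is not None and page_id in covering.get(topic, set())
            p = config.sensitivity if truly else config.false_positive_rate
            for r in range(config.n_raters):
                rows.append(RatingRow(
                    query_id=result.query_id, page_id=page_id,
                    rater_id=f"rater{r + 1}", relevant=bool(rng.random() < p),
                ))
    return RatingTable(tuple(rows))
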