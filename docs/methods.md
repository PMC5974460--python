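# Methods

This note records the models, conventions, and design choices behind
`needgap`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Corpus model

The unit of analysis is the *sentence-type unit*. Posts are split by a
rule-based segmenter (boundaries at `.`, `!`, `?`, and newlines) with a
packaged abbreviation list; a period after a single letter (initials,
`e.g.`) or inside a decimal number is not a boundary, and runs of
terminators (`...`, `?!`) stay with their sentence. The tokenizer
lowercases, splits on whitespace, and strips edge punctuation while keeping
internal apostrophes and hyphens — informal forum text is full of
contractions and compounds (`don't`, `follow-up`), and a stable tokenizer
keeps bigram patterns reproducible.

Annotations: one or two categories per sentence from the fixed ten-way
taxonomy plus a binary HASN flag. Two dialects reflect the two annotation
campaigns the data model supports: `MC` (one category, catch-all `multiple`
admissible) and `CSN` (up to two categories, no `multiple`).

Conventions chosen where several were defensible:

* **Standard deviations** are sample SDs (n − 1 denominator).
* **Word counts** include every token the tokenizer emits (pure-punctuation
  tokens vanish, so stray punctuation does not inflate lengths).
* **Category fractions**: each sentence contributes one count to *each* of
  its labels with the number of sentences as the denominator, so two-label
  corpora may have fractions summing above 1. This matches per-category
  count columns computed over total sentences.
* **`multiple` sentences** are excluded from both the positive and the
  negative side of every one-vs-rest classification problem: the class is a
  coding artifact, not an information type.

## Rule induction over the cue vocabulary

The cue vocabulary *V* (packaged default, ~70 lowercased words:
wh-words, auxiliaries, pronouns, and request words such as *wondering*,
*advice*, *anyone*) defines the candidate space. For each positive training
sentence not already matched by an accepted pattern, the algorithm searches
subsets of the sentence's adjacent V-bigrams by increasing cardinality and,
within one cardinality, lexicographically over the bigrams sorted by
sentence position; the first subset contained in the positive and in no
negative becomes a pattern. Positives are processed in corpus order (the
loop is order-dependent, and corpus order is the only natural order).
Identical patterns are deduplicated by construction — a positive matched by
an earlier pattern is skipped and recorded in that pattern's multiplicity.

The subset search is capped at four bigrams: the cap bounds the worst-case
cost and larger conjunctions memorize individual training sentences rather
than generalize. A positive with no separating subset within the cap is
recorded as *unseparable*. Greedy first-acceptance at increasing
cardinality guarantees minimality: no proper subset of an accepted pattern
separates, because it would have been found earlier.

## Classifier features and evaluation

* **Words and bigrams**: occurrence counts over a vocabulary frozen on the
  training split; terms with fewer than `min_term_count = 2` total training
  occurrences are dropped to bound dimensionality.
* **Local context**: for each of the ten categories, a binary indicator for
  the label(s) of the immediately preceding and following sentences in
  conversation order (all zeros at conversation boundaries; two-label
  neighbours set both bits). By default these come from gold labels — the
  configuration the published-style evaluation uses — with
  `context_source="predicted"` reserved for sequential decoding in a
  production setting where gold neighbours do not exist.
* **Topic proportions**: latent Dirichlet allocation fitted on the training
  sentences only, default 50 topics with 15 words reported per topic. The
  feature value is the share of the sentence's tokens attributed to a
  topic; empty or fully out-of-vocabulary sentences get an all-zero block.
  Priors are symmetric: topic-word β = 0.01 and document-topic
  α = min(1, 50/T) — the classic 50/T heuristic, capped at 1 because the
  variational parameterization used for inference requires α ≤ 1; at the
  default T = 50 the cap is inactive.
* **Embeddings**: the element-wise mean of the word vectors of in-table
  tokens (zero vector if none), from any plain-text `word v1 ... vD` table.
  A small deterministic toy table ships for tests; nothing is downloaded.

Learners: multinomial Naive Bayes on counts; linear SVM with C = 1; random
forest with 100 trees and default feature subsampling, all seeded. The
learners are named with deliberately standard hyperparameters — the
comparisons of interest are between feature families, not tuned learners.

Cross-validation is stratified k-fold (default k = 10) with the vocabulary
manifest and topic model refitted per fold on the training portion.
Positive-class confusion counts are pooled across folds before computing
precision/recall/F (micro-averaging): with rare categories, per-fold
averaging of ill-defined ratios is unstable. Metrics are reported for the
positive class, as befits one-vs-rest problems. Cross-forum transfer fits
everything on one corpus and evaluates on the other, each corpus supplying
its own gold neighbour labels.

The binary HASN detector trains on the combined corpora with words and
bigrams only, and is evaluated on a held-out corpus via the same
positive-class metrics, with zero-denominator cases reported as 0 plus an
explicit warning flag.

## Concept profiling

Concept tagging is greedy longest-match left-to-right over tokens with
surface terms of one to three tokens; matches never overlap. Ranking sums
counts over the sentences carrying a category and breaks ties
alphabetically, so the output is a deterministic function of the counts.
Plain counts order the ranking — no tagger-internal scoring is assumed —
and the packaged ~150-entry breast-cancer lexicon exists to exercise the
pipeline; users with access to a licensed medical thesaurus can supply
their own `term,concept` table.

## Gap assessment

*Selection.* A need sentence is dropped as a duplicate when it is labelled
`previous` and immediately follows (same post, adjacent position) another
need sentence: it restates the preceding need. A `previous` need that is
not a duplicate is resolved to the nearest sentence in the conversation —
absolute sentence distance, ties preferring the preceding sentence — that
carries at least one category other than `social`/`previous`; query terms
come *only* from that antecedent, never concatenated with the referential
sentence. Distance is measured in sentences rather than posts, the finer
and less ambiguous unit. If no antecedent exists the sentence itself is
used, with a warning.

*Queries.* Stop-words (packaged ~190-word list: a standard English list
plus forum artifacts like *hi*, *thanks*) are removed; the remaining terms
are scored tf·idf with raw counts for tf and idf = ln((N + 1)/(df + 1)) + 1.
The idf collection is the education-page index by default — query terms are
weighted by rarity in the collection being searched — with corpus-based idf
available as a switch. The top ten terms are kept, ties alphabetical.

*Retrieval.* Whole pages are single retrieval units (indexing subsections
would overstate gaps whenever query terms span units). Okapi BM25 with
k₁ = 1.2, b = 0.75 and idf(t) = ln(1 + (N − df + 0.5)/(df + 0.5)) — the
default behaviour of the mainstream search engines — scores each distinct
query term once; the top two pages are kept (preliminary inspection
motivates the cutoff; it is configurable upward), ties by page id.

*Statistics.* Percent agreement is the chance-uncorrected fraction of rated
documents with identical verdicts (pairwise mean with a flag when more than
two raters rate). Coverage-any / coverage-all are fractions of queries with
at least one document marked relevant by at least one / by every rater;
coverage-all ≤ coverage-any holds by construction and is property-tested.

## Synthetic data: what it emulates, and what it does not

The generator draws post, sentence, and word counts from rounded normal
distributions truncated at 1 — the emulated data report only means and SDs,
and a truncated rounded normal is the least-structured choice matching
them. Two profiles package the published descriptive statistics: `MC`
(6.35 ± 4.42 sentences/post, 14.04 ± 6.30 words/sentence, category mixture
normalized from the published per-category counts, per-category HASN rates
from the published need distribution) and `CSN` (11.52 ± 5.29,
13.97 ± 5.30, second category attached with probability 0.10, since the
published label counts exceed the sentence count by ~10%). Posts per
conversation are not reported for either forum; the MC default of
4.7 ± 2.5 reproduces ~1943 sentences from 65 conversations. An optional
exact sentence-count target trims the overshoot of the last post so
calibration runs use precisely the published corpus size.

Sentences are template realizations: each category owns a bank of exclusive
content words, all categories share filler words, and a HASN sentence is a
wh-question or an indirect statement in equal proportion (one indirect
variant drops the subject — "curious whether anybody tried ..." — and
contains no adjacent cue-vocabulary pair, reproducing the known blind spot
of bigram patterns). Referential sentences contain a referring cue
(*this/that/it*) and no content word; after a need sentence, a referential
restatement follows with probability `previous_follow_rate`, which is what
duplicate removal consumes. Optional dials add label autocorrelation
(`category_stickiness`, a Markov repeat probability) and vocabulary noise
(`vocab_noise`, the probability a content slot is filled from another
bank); both default to 0 and exist to create the regimes where local
context helps and where text features are imperfect.

Education pages are filler text with the vocabulary of a *covered* topic
planted in dedicated pages; exactly round(c · n_topics) topics are covered
at coverage fraction c, and a covering page carries most (two-thirds to
all) of its topic's bank, so the topic is findable through any of its
characteristic terms — coverage is defined at topic level, and a page
mentioning only a sliver of the vocabulary would not cover the topic in
any usable sense. Uncovered topics appear in no page. Simulated raters mark
a truly covering page relevant with probability `sensitivity` and any other
page with probability `false_positive_rate`, independently per rater and
document. One global seed drives three independent sub-streams (corpus,
pages, raters), so stages can be rerun in isolation.

What passing tests on this data do **not** show: the generator's sentences
are bags of template slots, not natural language — there is no syntax, no
misspelling, no topic drift within a conversation, no author style, and the
category-exclusive vocabulary makes classification far easier than on real
forum text (the classifier suite reaches near-perfect F on noiseless
configurations; published-style mid-range scores only appear under the
vocabulary-noise dial). The benchmarks validate the *machinery* —
bookkeeping, feature construction, fold hygiene, ranking arithmetic,
statistic definitions — not real-world accuracy.

## Test problem sizes

The suite exercises the statistical properties at sizes chosen to give
stable verdicts: mixture convergence on 5000 sentences (χ² at α = 0.01),
calibration on the published 1943-sentence size, coverage recovery on
1400-sentence balanced corpora with 30 pages across planted fractions
{0, .25, .5, .75, 1} (tolerance ±0.1), the local-context ablation on ten
350-sentence corpora with stickiness 0.7 and vocabulary noise 0.55
(one-sided Wilcoxon), and rule/BM25 oracle equivalence on dozens of
randomized small instances. All randomness is seeded; reruns are
deterministic.

## Known limitations

* The sentence segmenter is rule-based; unusual abbreviations or emoticons
  can split or merge units.
* Gold-label local context leaks neighbour annotations by design (it
  mirrors the evaluation setting it emulates); production use requires
  `context_source="predicted"` or a sequence model, which is out of scope.
* The concept lexicon is a small curated stand-in, not a licensed medical
  thesaurus; longest-match tagging does no disambiguation or negation
  handling.
* Queries are not expanded with synonyms, so measured gaps are upper
  bounds whenever education materials use different terminology than
  patients do.
* BM25 is implemented directly (no search-engine service); scores follow
  the standard formula, not any particular engine version's quirks.
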