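"""Sentence classification: features, one-vs-rest training, evaluation.

Each information category gets its own binary (one-versus-the-others)
classifier.  Input features are any combination of:

* word and bigram occurrence counts over a vocabulary frozen on the
  training split (terms below ``min_term_count`` total occurrences are
  dropped);
* local context: binary indicators for each category label of the
  immediately preceding and following sentences in the conversation
  (all-zero blocks at conversation boundaries);
* topic proportions from a latent Dirichlet allocation model fitted on the
  training sentences: per topic, the fraction of the sentence's tokens
  attributed to that topic;
* averaged word embeddings from a user-supplied plain-text vector table.

Evaluation uses stratified k-fold cross-validation with the vocabulary and
topic model refitted on each training portion, pooling the positive-class
confusion counts across folds (micro-averaging).  Sentences labelled
``multiple`` are excluded from both sides of every per-category problem.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC

from .corpus import CATEGORIES, MULTIPLE, Corpus, Sentence, bigrams
from .rules import BinaryMetrics, evaluate_binary

LEARNERS = ("naive_bayes", "linear_svm", "random_forest")


# --------------------------------------------------------------------------
# feature specification

@dataclass(frozen=True)
class FeatureSpec:
    use_words: bool = True
    use_bigrams: bool = True
    use_local_context: bool = False
    context_source: str = "gold"  # or "predicted"
    use_topics: bool = False
    n_topics: int = 50
    words_per_topic: int = 15  # reporting only
    use_embeddings: bool = False
    embedding_dim: int = 50
    min_term_count: int = 2

    def __post_init__(self) -> None:
        if not (self.use_words or self.use_bigrams or self.use_local_context
                or self.use_topics or self.use_embeddings):
            raise ValueError("at least one feature family must be enabled")
        if self.context_source not in ("gold", "predicted"):
            raise ValueError(f"unknown context_source {self.context_source!r}")


@dataclass(frozen=True)
class FeatureVector:
    """Named sparse realization of one sentence's features."""

    sentence_id: str
    values: Mapping[str, float]


@dataclass(frozen=True)
class EvalReport:
    category: str
    learner: str
    spec: FeatureSpec
    seed: int
    precision: float
    recall: float
    f1: float
    n_positive: int
    n_sentences: int
    fold_sizes: tuple[int, ...] = ()


# --------------------------------------------------------------------------
# word-vector table

class VectorTable:
    """Word vectors in the plain-text ``word v1 ... vD`` format."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        dims = {v.shape[0] for v in vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent vector dimensions in table: {sorted(dims)}")
        self.vectors = dict(vectors)
        self.dim = dims.pop() if dims else 0

    @classmethod
    def from_file(cls, path: str | Path) -> "VectorTable":
        vectors: dict[str, np.ndarray] = {}
        dim: int | None = None
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            parts = line.split()
            if not parts:
                continue
            word, vals = parts[0], parts[1:]
            vec = np.array([float(v) for v in vals])
            if dim is None:
                dim = vec.shape[0]
            elif vec.shape[0] != dim:
                raise ValueError(
                    f"{path}:{lineno}: vector for {word!r} has {vec.shape[0]} "
                    f"dimensions, expected {dim}"
                )
            vectors[word] = vec
        return cls(vectors)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors


def embedding_features(sentence: Sentence | Sequence[str], table: VectorTable) -> np.ndarray:
    """Elementwise mean of the vectors of in-table tokens; zero if none."""
    tokens = sentence.tokens if isinstance(sentence, Sentence) else list(sentence)
    vecs = [table.vectors[t] for t in tokens if t in table]
    if not vecs:
        return np.zeros(table.dim)
    return np.mean(vecs, axis=0)


# --------------------------------------------------------------------------
# topic model

def assignment_fractions(assignments: Sequence[int], n_topics: int) -> np.ndarray:
    """Per-topic fraction of tokens given explicit token-topic assignments."""
    out = np.zeros(n_topics)
    if not assignments:
        return out
    for t in assignments:
        out[t] += 1
    return out / len(assignments)


class TopicModel:
    """LDA over sentence token lists; features are per-topic token fractions.

    Priors are symmetric (doc-topic 50/T, topic-word 0.01); inference is
    variational.  Transforming an empty or fully out-of-vocabulary sentence
    yields an all-zero block; otherwise the topic values sum to 1.
    """

    def __init__(self, n_topics: int = 50, seed: int = 0, max_iter: int = 30):
        self.n_topics = n_topics
        self.seed = seed
        self.max_iter = max_iter
        self.vocabulary: dict[str, int] = {}
        self._lda: LatentDirichletAllocation | None = None

    def _counts(self, token_lists: Sequence[Sequence[str]]) -> sp.csr_matrix:
        rows, cols, data = [], [], []
        for i, toks in enumerate(token_lists):
            counts = Counter(t for t in toks if t in self.vocabulary)
            for t, c in counts.items():
                rows.append(i)
                cols.append(self.vocabulary[t])
                data.append(c)
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(len(token_lists), len(self.vocabulary))
        )

    def fit(self, token_lists: Sequence[Sequence[str]]) -> "TopicModel":
        vocab = sorted({t for toks in token_lists for t in toks})
        self.vocabulary = {w: i for i, w in enumerate(vocab)}
        # classic symmetric-prior heuristic alpha = 50/T, capped at 1.0 (the
        # variational parameterization requires alpha <= 1); equal to 50/T at
        # the default T = 50
        self._lda = LatentDirichletAllocation(
            n_components=self.n_topics,
            doc_topic_prior=min(1.0, 50.0 / self.n_topics),
            topic_word_prior=0.01,
            max_iter=self.max_iter,
            learning_method="batch",
            random_state=self.seed,
        )
        X = self._counts(token_lists)
        if X.sum() == 0:
            raise ValueError("cannot fit a topic model on empty token lists")
        self._lda.fit(X)
        return self

    def transform(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        if self._lda is None:
            raise RuntimeError("topic model not fitted")
        X = self._counts(token_lists)
        out = np.zeros((len(token_lists), self.n_topics))
        lengths = np.asarray(X.sum(axis=1)).ravel()
        nonempty = np.flatnonzero(lengths > 0)
        if nonempty.size:
            out[nonempty] = self._lda.transform(X[nonempty])
        return out

    def top_words(self, n_words: int | None = None) -> list[list[str]]:
        if self._lda is None:
            raise RuntimeError("topic model not fitted")
        n_words = n_words or 15
        inv = {i: w for w, i in self.vocabulary.items()}
        topics = []
        for comp in self._lda.components_:
            order = np.argsort(comp)[::-1][:n_words]
            topics.append([inv[i] for i in order])
        return topics


# --------------------------------------------------------------------------
# local context

Neighbors = Mapping[str, tuple[frozenset[str] | None, frozenset[str] | None]]


def conversation_neighbors(corpus: Corpus) -> dict[str, tuple[frozenset[str] | None, frozenset[str] | None]]:
    """Gold category sets of the immediately preceding/following sentence in
    conversation order (None at conversation boundaries)."""
    out: dict[str, tuple[frozenset[str] | None, frozenset[str] | None]] = {}
    for conv in corpus.conversations:
        flat = list(conv.sentences())
        for i, s in enumerate(flat):
            prev = flat[i - 1].categories if i > 0 else None
            nxt = flat[i + 1].categories if i + 1 < len(flat) else None
            out[s.sentence_id] = (prev, nxt)
    return out


_CONTEXT_SLOTS = [c for c in CATEGORIES]


def local_context_features(sentence: Sentence, neighbors: Neighbors) -> np.ndarray:
    """2 x |categories| binary indicators for the neighbour labels."""
    prev, nxt = neighbors.get(sentence.sentence_id, (None, None))
    vec = np.zeros(2 * len(_CONTEXT_SLOTS))
    if prev:
        for c in prev:
            vec[_CONTEXT_SLOTS.index(c)] = 1.0
    if nxt:
        for c in nxt:
            vec[len(_CONTEXT_SLOTS) + _CONTEXT_SLOTS.index(c)] = 1.0
    return vec


def context_feature_names() -> list[str]:
    return [f"ctx:prev:{c}" for c in _CONTEXT_SLOTS] + [f"ctx:next:{c}" for c in _CONTEXT_SLOTS]


# --------------------------------------------------------------------------
# design matrix

class FeatureBuilder:
    """Fits the feature manifest on training sentences only, then realizes
    feature matrices for any sentence list (no test-split leakage)."""

    def __init__(self, spec: FeatureSpec, seed: int = 0,
                 vector_table: VectorTable | None = None):
        if spec.use_embeddings and vector_table is None:
            raise ValueError("use_embeddings requires a vector table")
        self.spec = spec
        self.seed = seed
        self.vector_table = vector_table
        self.word_vocab: dict[str, int] = {}
        self.bigram_vocab: dict[tuple[str, str], int] = {}
        self.topic_model: TopicModel | None = None
        self._fitted = False

    def fit(self, sentences: Sequence[Sentence]) -> "FeatureBuilder":
        spec = self.spec
        if spec.use_words:
            counts: Counter[str] = Counter()
            for s in sentences:
                counts.update(s.tokens)
            vocab = sorted(t for t, c in counts.items() if c >= spec.min_term_count)
            self.word_vocab = {t: i for i, t in enumerate(vocab)}
        if spec.use_bigrams:
            bcounts: Counter[tuple[str, str]] = Counter()
            for s in sentences:
                bcounts.update(bigrams(s.tokens))
            bvocab = sorted(b for b, c in bcounts.items() if c >= spec.min_term_count)
            self.bigram_vocab = {b: i for i, b in enumerate(bvocab)}
        if spec.use_topics:
            self.topic_model = TopicModel(spec.n_topics, seed=self.seed).fit(
                [s.tokens for s in sentences]
            )
        self._fitted = True
        return self

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        if self.spec.use_words:
            names += [f"w:{t}" for t in sorted(self.word_vocab, key=self.word_vocab.get)]
        if self.spec.use_bigrams:
            names += [f"b:{a}_{b}" for a, b in sorted(self.bigram_vocab, key=self.bigram_vocab.get)]
        if self.spec.use_local_context:
            names += context_feature_names()
        if self.spec.use_topics:
            names += [f"topic:{i}" for i in range(self.spec.n_topics)]
        if self.spec.use_embeddings:
            dim = self.vector_table.dim if self.vector_table else self.spec.embedding_dim
            names += [f"emb:{i}" for i in range(dim)]
        return names

    def manifest_checksum(self) -> str:
        h = hashlib.sha256()
        for name in self.feature_names:
            h.update(name.encode("utf-8"))
            h.update(b"\0")
        return h.hexdigest()

    def transform(self, sentences: Sequence[Sentence],
                  neighbors: Neighbors | None = None) -> sp.csr_matrix:
        if not self._fitted:
            raise RuntimeError("FeatureBuilder not fitted")
        spec = self.spec
        blocks: list[sp.spmatrix] = []
        n = len(sentences)
        if spec.use_words:
            rows, cols, data = [], [], []
            for i, s in enumerate(sentences):
                for t, c in Counter(s.tokens).items():
                    j = self.word_vocab.get(t)
                    if j is not None:
                        rows.append(i), cols.append(j), data.append(c)
            blocks.append(sp.csr_matrix((data, (rows, cols)), shape=(n, len(self.word_vocab))))
        if spec.use_bigrams:
            rows, cols, data = [], [], []
            for i, s in enumerate(sentences):
                for b, c in Counter(bigrams(s.tokens)).items():
                    j = self.bigram_vocab.get(b)
                    if j is not None:
                        rows.append(i), cols.append(j), data.append(c)
            blocks.append(sp.csr_matrix((data, (rows, cols)), shape=(n, len(self.bigram_vocab))))
        if spec.use_local_context:
            if neighbors is None:
                raise ValueError("local-context features need a neighbour mapping")
            ctx = np.vstack([local_context_features(s, neighbors) for s in sentences]) \
                if n else np.zeros((0, 2 * len(_CONTEXT_SLOTS)))
            blocks.append(sp.csr_matrix(ctx))
        if spec.use_topics:
            assert self.topic_model is not None
            blocks.append(sp.csr_matrix(self.topic_model.transform([s.tokens for s in sentences])))
        if spec.use_embeddings:
            assert self.vector_table is not None
            emb = np.vstack([embedding_features(s, self.vector_table) for s in sentences]) \
                if n else np.zeros((0, self.vector_table.dim))
            blocks.append(sp.csr_matrix(emb))
        return sp.hstack(blocks, format="csr")


def build_design_matrix(
    corpus: Corpus,
    spec: FeatureSpec,
    seed: int = 0,
    vector_table: VectorTable | None = None,
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Fit on the whole corpus and realize its design matrix.

    Returns ``(X, feature_names, sentence_ids)``.  For leakage-free
    evaluation use :class:`FeatureBuilder` fitted per training split instead.
    """
    sentences = list(corpus.sentences())
    builder = FeatureBuilder(spec, seed=seed, vector_table=vector_table).fit(sentences)
    neighbors = conversation_neighbors(corpus) if spec.use_local_context else None
    X = builder.transform(sentences, neighbors)
    return X, builder.feature_names, [s.sentence_id for s in sentences]


def to_feature_vectors(X: sp.csr_matrix, names: Sequence[str],
                       sentence_ids: Sequence[str]) -> list[FeatureVector]:
    out = []
    for i, sid in enumerate(sentence_ids):
        row = X.getrow(i)
        out.append(FeatureVector(sid, {names[j]: float(v) for j, v in zip(row.indices, row.data)}))
    return out


# --------------------------------------------------------------------------
# learners and cross-validation

def make_learner(name: str, seed: int = 0):
    if name == "naive_bayes":
        return MultinomialNB()
    if name == "linear_svm":
        return LinearSVC(C=1.0, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown learner {name!r}; expected one of {LEARNERS}")


def _eligible_sentences(corpus: Corpus) -> list[Sentence]:
    # 'multiple' sentences leave every one-vs-rest problem entirely
    return [s for s in corpus.sentences() if MULTIPLE not in s.categories]


def _labels(sentences: Sequence[Sentence], category: str) -> np.ndarray:
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return np.array([category in s.categories for s in sentences], dtype=bool)


def cross_validate(
    corpus: Corpus,
    category: str,
    learner: str,
    spec: FeatureSpec,
    k: int = 10,
    seed: int = 0,
    vector_table: VectorTable | None = None,
) -> EvalReport:
    """One-vs-rest stratified k-fold cross-validation for one category.

    The vocabulary manifest and topic model are refitted on each fold's
    training portion; confusion counts are pooled over folds before
    computing positive-class precision/recall/F.
    """
    sentences = _eligible_sentences(corpus)
    y = _labels(sentences, category)
    n_pos = int(y.sum())
    if n_pos < k:
        raise ValueError(
            f"category {category!r} has only {n_pos} positive sentences; "
            f"need at least k={k} for stratified folds"
        )
    neighbors = conversation_neighbors(corpus) if spec.use_local_context else None
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tp = fp = fn = 0
    fold_sizes = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = [sentences[i] for i in train_idx]
        test = [sentences[i] for i in test_idx]
        builder = FeatureBuilder(spec, seed=seed, vector_table=vector_table).fit(train)
        Xtr = builder.transform(train, neighbors)
        Xte = builder.transform(test, neighbors)
        clf = make_learner(learner, seed)
        clf.fit(Xtr, y[train_idx])
        pred = np.asarray(clf.predict(Xte), dtype=bool)
        gold = y[test_idx]
        tp += int(np.sum(pred & gold))
        fp += int(np.sum(pred & ~gold))
        fn += int(np.sum(~pred & gold))
        fold_sizes.append(len(train_idx))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(category, learner, spec, seed, precision, recall, f1,
                      n_pos, len(sentences), tuple(fold_sizes))


def cross_forum_eval(
    train_corpus: Corpus,
    test_corpus: Corpus,
    category: str,
    learner: str,
    spec: FeatureSpec,
    seed: int = 0,
    vector_table: VectorTable | None = None,
) -> EvalReport:
    """Train on one forum corpus, evaluate on the other.

    The manifest and topic model are fitted on the training corpus only;
    local-context features for each corpus come from that corpus's own gold
    labels.
    """
    train = _eligible_sentences(train_corpus)
    test = _eligible_sentences(test_corpus)
    y_train = _labels(train, category)
    y_test = _labels(test, category)
    builder = FeatureBuilder(spec, seed=seed, vector_table=vector_table).fit(train)
    nb_train = conversation_neighbors(train_corpus) if spec.use_local_context else None
    nb_test = conversation_neighbors(test_corpus) if spec.use_local_context else None
    clf = make_learner(learner, seed)
    clf.fit(builder.transform(train, nb_train), y_train)
    pred = np.asarray(clf.predict(builder.transform(test, nb_test)), dtype=bool)
    m = evaluate_binary(pred.tolist(), y_test.tolist())
    return EvalReport(category, learner, spec, seed, m.precision, m.recall, m.f1,
                      int(y_test.sum()), len(test))


# --------------------------------------------------------------------------
# binary information-need (HASN) classifier

DEFAULT_HASN_SPEC = FeatureSpec(use_words=True, use_bigrams=True, min_term_count=2)


@dataclass
class HasnModel:
    builder: FeatureBuilder
    clf: object
    learner: str

    def predict(self, corpus: Corpus) -> list[bool]:
        sentences = list(corpus.sentences())
        X = self.builder.transform(sentences)
        return [bool(v) for v in self.clf.predict(X)]


def train_hasn_classifier(
    corpora: Sequence[Corpus],
    learner: str = "random_forest",
    spec: FeatureSpec = DEFAULT_HASN_SPEC,
    seed: int = 0,
) -> HasnModel:
    """Train the binary need detector on the combined corpora
    (words + bigrams by default)."""
    sentences = [s for c in corpora for s in c.sentences()]
    y = np.array([s.hasn for s in sentences], dtype=bool)
    builder = FeatureBuilder(spec, seed=seed).fit(sentences)
    clf = make_learner(learner, seed)
    clf.fit(builder.transform(sentences), y)
    return HasnModel(builder, clf, learner)


def evaluate_hasn(model: HasnModel, corpus: Corpus) -> BinaryMetrics:
    gold = [s.hasn for s in corpus.sentences()]
    return evaluate_binary(model.predict(corpus), gold)


# --------------------------------------------------------------------------
# report output

def write_eval_reports(reports: Sequence[EvalReport], path: str | Path) -> None:
    """CSV mirroring the category x (P, R, F) x (without, with context) layout."""
    import csv

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category", "learner", "local_context",
                         "precision", "recall", "f_measure", "n_positive"])
        for r in reports:
            writer.writerow([
                r.category, r.learner,
                "with" if r.spec.use_local_context else "without",
                f"{r.precision:.2f}", f"{r.recall:.2f}", f"{r.f1:.2f}", r.n_positive,
            ])
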