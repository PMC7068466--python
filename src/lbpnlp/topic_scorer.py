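"""TopicModel: LDA document scoring against an acuity-keyword topic set.

Fits latent Dirichlet allocation on the training notes, ranks topics by their
posterior probability given a set of acuity keywords (acute, low, back, pain,
lbp, bp), retains a reviewed subset of topics (or the top-m ranked as a
non-interactive fallback), and scores each note by the maximum inferred
probability among the retained topics.

LDA estimation and document-topic inference are delegated to scikit-learn's
variational implementation; ranking, retention and scoring logic live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from .text_processing import ProcessedNote, Vocabulary

logger = logging.getLogger(__name__)

#: Acuity keywords used to rank topics.
DEFAULT_TOPIC_KEYWORDS = ("acute", "low", "back", "pain", "lbp", "bp")


def _count_matrix(
    token_lists: Sequence[Sequence[str]], term_to_index: dict[str, int]
) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for i, toks in enumerate(token_lists):
        counts: dict[int, int] = {}
        for t in toks:
            j = term_to_index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(token_lists), len(term_to_index))
    )


@dataclass
class TopicModelState:
    """A fitted LDA model with its vocabulary and retained-topic set."""

    K: int
    term_to_index: dict[str, int]
    topic_word: np.ndarray          # (K, V), rows sum to 1
    topic_prior: np.ndarray         # (K,), empirical mean doc-topic mass
    lda: LatentDirichletAllocation
    seed: int
    retained_topic_ids: frozenset[int] = field(default_factory=frozenset)
    perplexity: float | None = None

    def infer_doc_topic(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        """Infer normalized document-topic distributions (rows sum to 1)."""
        X = _count_matrix(token_lists, self.term_to_index)
        theta = self.lda.transform(X)
        return theta / theta.sum(axis=1, keepdims=True)


def fit_lda(
    corpus_tokens: Sequence[Sequence[str]],
    vocab: Vocabulary,
    K: int = 200,
    seed: int = 0,
    max_iter: int = 15,
    doc_topic_prior: float | None = None,
    topic_word_prior: float = 0.01,
    heldout_fraction: float = 0.0,
) -> TopicModelState:
    """Fit LDA with K topics on token lists encoded against ``vocab``.

    Defaults use symmetric Dirichlet hyperparameters alpha = 1/K and
    beta = 0.01. With ``heldout_fraction`` > 0 the last fraction of documents
    is held out and their perplexity reported (to support choosing K);
    otherwise training perplexity is reported.
    """
    if not corpus_tokens:
        raise ValueError("corpus must be non-empty")
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > len(corpus_tokens):
        logger.warning("K=%d exceeds number of documents (%d)", K, len(corpus_tokens))
    if doc_topic_prior is None:
        doc_topic_prior = 1.0 / K
    X = _count_matrix(corpus_tokens, vocab.term_to_index)
    n_fit = len(corpus_tokens)
    if heldout_fraction > 0:
        n_fit = max(1, int(round(len(corpus_tokens) * (1 - heldout_fraction))))
    lda = LatentDirichletAllocation(
        n_components=K,
        doc_topic_prior=doc_topic_prior,
        topic_word_prior=topic_word_prior,
        max_iter=max_iter,
        random_state=seed,
        learning_method="batch",
    )
    lda.fit(X[:n_fit])
    X_eval = X[n_fit:] if n_fit < X.shape[0] else X
    perplexity = float(lda.perplexity(X_eval)) if X_eval.shape[0] else None
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    theta = lda.transform(X[:n_fit])
    theta = theta / theta.sum(axis=1, keepdims=True)
    topic_prior = theta.mean(axis=0)
    topic_prior = topic_prior / topic_prior.sum()
    return TopicModelState(
        K=K,
        term_to_index=dict(vocab.term_to_index),
        topic_word=topic_word,
        topic_prior=topic_prior,
        lda=lda,
        seed=seed,
        perplexity=perplexity,
    )


def rank_topics_for_keywords(
    model: TopicModelState,
    keywords: Sequence[str] = DEFAULT_TOPIC_KEYWORDS,
    uniform_prior: bool = False,
) -> list[tuple[int, float]]:
    """Rank topics by relevance(k) = sum over keywords of p(topic k | word).

    p(k|w) is computed by Bayes' rule from the topic-word distributions and
    the model's topic prior (empirical doc-topic mass; ``uniform_prior`` uses
    1/K instead). Out-of-vocabulary keywords are skipped with a warning;
    if none is in vocabulary this is an error.
    """
    prior = np.full(model.K, 1.0 / model.K) if uniform_prior else model.topic_prior
    relevance = np.zeros(model.K)
    n_used = 0
    for w in keywords:
        j = model.term_to_index.get(w)
        if j is None:
            logger.warning("keyword %r not in vocabulary; skipped", w)
            continue
        joint = model.topic_word[:, j] * prior
        total = joint.sum()
        if total == 0:
            # the word has zero mass everywhere except possibly nowhere;
            # contributes its posterior only where defined
            continue
        relevance += joint / total
        n_used += 1
    if n_used == 0:
        raise ValueError("no topic keyword is in the vocabulary")
    order = sorted(range(model.K), key=lambda k: (-relevance[k], k))
    return [(k, float(relevance[k])) for k in order]


def retain_topics(model: TopicModelState, topic_ids: Sequence[int]) -> TopicModelState:
    """Record the reviewed retained-topic set on the model state."""
    ids = frozenset(int(i) for i in topic_ids)
    if not ids:
        raise ValueError("retained topic set must be non-empty")
    for i in ids:
        if not (0 <= i < model.K):
            raise ValueError(f"topic id {i} out of range [0, {model.K})")
    model.retained_topic_ids = ids
    return model


def retain_top_m(
    model: TopicModelState,
    m: int = 3,
    keywords: Sequence[str] = DEFAULT_TOPIC_KEYWORDS,
    uniform_prior: bool = False,
) -> TopicModelState:
    """Non-interactive fallback for manual review: keep the top-m ranked topics."""
    ranked = rank_topics_for_keywords(model, keywords, uniform_prior=uniform_prior)
    return retain_topics(model, [k for k, _ in ranked[:m]])


def topic_score(model: TopicModelState, note_tokens: Sequence[str]) -> float:
    """Score = max retained-topic probability of the note (0 for empty notes)."""
    if not model.retained_topic_ids:
        raise ValueError("retained topic set is empty; call retain_topics first")
    if not note_tokens:
        logger.warning("empty note scored as 0")
        return 0.0
    theta = model.infer_doc_topic([list(note_tokens)])[0]
    ids = sorted(model.retained_topic_ids)
    return float(theta[ids].max())


def topic_scores(
    model: TopicModelState, notes_tokens: Sequence[Sequence[str]]
) -> np.ndarray:
    """Vectorized :func:`topic_score` over many notes."""
    if not model.retained_topic_ids:
        raise ValueError("retained topic set is empty; call retain_topics first")
    nonempty = [i for i, t in enumerate(notes_tokens) if t]
    out = np.zeros(len(notes_tokens))
    if nonempty:
        theta = model.infer_doc_topic([list(notes_tokens[i]) for i in nonempty])
        ids = sorted(model.retained_topic_ids)
        out[nonempty] = theta[:, ids].max(axis=1)
    return out


def topic_report(
    model: TopicModelState,
    keywords: Sequence[str] = DEFAULT_TOPIC_KEYWORDS,
    top_words: int = 20,
) -> str:
    """TSV report: topic_id, relevance, top words with probabilities."""
    terms = [""] * len(model.term_to_index)
    for t, i in model.term_to_index.items():
        terms[i] = t
    lines = ["topic_id\trelevance\ttop_words"]
    for k, rel in rank_topics_for_keywords(model, keywords):
        top = np.argsort(-model.topic_word[k])[:top_words]
        words = " ".join(f"{terms[j]}:{model.topic_word[k, j]:.4f}" for j in top)
        lines.append(f"{k}\t{rel:.6f}\t{words}")
    return "\n".join(lines) + "\n"


def save_retained_ids(model: TopicModelState, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{i}\n" for i in sorted(model.retained_topic_ids)), encoding="utf-8"
    )


def load_retained_ids(path: str | Path) -> list[int]:
    return [int(x) for x in Path(path).read_text().split()]


class TopicModelScorer:
    """Benchmark adapter: LDA scorer with the top-m retention fallback.

    Labels are ignored (unsupervised); per-fold manually reviewed retained-id
    files can be supplied instead of the top-m fallback.
    """

    name = "topicmodel"
    needs_embeddings = False

    def __init__(
        self,
        K: int = 200,
        top_m: int = 3,
        keywords: Sequence[str] = DEFAULT_TOPIC_KEYWORDS,
        max_iter: int = 15,
        retained_ids: Sequence[int] | None = None,
    ) -> None:
        self.K = K
        self.top_m = top_m
        self.keywords = tuple(keywords)
        self.max_iter = max_iter
        self.retained_ids = retained_ids
        self.state: TopicModelState | None = None

    def fit(self, notes, labels=None, val_notes=None, val_labels=None, *,
            vocab: Vocabulary, seed: int = 0, embeddings=None) -> "TopicModelScorer":
        tokens = [n.tokens for n in notes]
        self.state = fit_lda(tokens, vocab, K=self.K, seed=seed,
                             max_iter=self.max_iter)
        if self.retained_ids is not None:
            retain_topics(self.state, self.retained_ids)
        else:
            retain_top_m(self.state, m=self.top_m, keywords=self.keywords)
        return self

    def score(self, notes: Sequence[ProcessedNote]) -> np.ndarray:
        if self.state is None:
            raise RuntimeError("fit must be called before score")
        return topic_scores(self.state, [n.tokens for n in notes])
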