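"""N-gram extraction, TF-IDF weighting and LASSO logistic regression."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import sparse

import lbpnlp as L
from lbpnlp.linear_models import (
    DEFAULT_STOPWORDS,
    extract_ngrams,
    fit_feature_space,
    load_lexicon,
    lr_score,
    tfidf_matrix,
    tfidf_vector,
    train_lasso_lr,
)


def test_extract_ngrams_enumeration():
    counts = extract_ngrams([("low", "back", "pain")], nmax=2,
                            stopwords=frozenset())
    assert counts == Counter({"low": 1, "back": 1, "pain": 1,
                              "low back": 1, "back pain": 1})


def test_extract_ngrams_stopwords_first_and_sentence_boundary():
    assert extract_ngrams([("the", "of", "and")], nmax=3) == Counter()
    counts = extract_ngrams([("a", "b"), ("c",)], nmax=2, stopwords=frozenset())
    assert "b c" not in counts


def test_idf_closed_forms():
    docs = [Counter({"g": 1}), Counter({"g": 1, "h": 1}), Counter({"g": 2})]
    space = fit_feature_space(docs)
    g, h = space.ngram_to_index["g"], space.ngram_to_index["h"]
    assert space.idf[g] == pytest.approx(math.log(4 / 4) + 1)  # df = N = 3
    assert space.idf[h] == pytest.approx(math.log(4 / 2) + 1)  # df = 1, N = 3


def test_lexicon_restriction_and_empty_intersection_error():
    docs = [Counter({"acute lbp": 1, "noise": 3})]
    space = fit_feature_space(docs, lexicon={"acute lbp"})
    assert set(space.ngram_to_index) == {"acute lbp"}
    with pytest.raises(ValueError):
        fit_feature_space(docs, lexicon={"absent phrase"})


def test_tfidf_zero_single_and_norm_invariant():
    docs = [Counter({"g": 1}), Counter({"h": 2})]
    space = fit_feature_space(docs)
    zero = tfidf_vector(Counter(), space)
    assert zero.nnz == 0
    single = tfidf_vector(Counter({"h": 2}), space).toarray().ravel()
    assert np.linalg.norm(single) == pytest.approx(1.0)
    X = tfidf_matrix([Counter({"g": 3, "h": 1}), Counter()], space)
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1))).ravel()
    assert all(n == pytest.approx(0.0) or n == pytest.approx(1.0) for n in norms)


def test_tfidf_agrees_with_bruteforce_oracle():
    """Explicit count*idf*normalize loop on a 5-document toy corpus."""
    rng = np.random.default_rng(3)
    grams = [f"g{i}" for i in range(8)]
    docs = [Counter({g: int(rng.integers(0, 4)) for g in grams
                     if rng.random() < 0.7}) for _ in range(5)]
    docs = [Counter({g: c for g, c in d.items() if c > 0}) for d in docs]
    space = fit_feature_space(docs)
    X = tfidf_matrix(docs, space).toarray()
    N = len(docs)
    for i, doc in enumerate(docs):
        row = np.zeros(len(space))
        for g, c in doc.items():
            df = sum(1 for d in docs if g in d)
            row[space.ngram_to_index[g]] = c * (math.log((1 + N) / (1 + df)) + 1)
        norm = np.linalg.norm(row)
        if norm > 0:
            row = row / norm
        assert np.allclose(X[i], row, atol=1e-10)


def test_tfidf_matches_sklearn_transformer():
    from sklearn.feature_extraction.text import TfidfTransformer

    rng = np.random.default_rng(4)
    counts = rng.integers(0, 5, size=(6, 9))
    docs = [Counter({f"g{j}": int(c) for j, c in enumerate(row) if c})
            for row in counts]
    space = fit_feature_space(docs)
    order = [space.ngram_to_index[f"g{j}"] for j in range(9)]
    ours = tfidf_matrix(docs, space).toarray()[:, order]
    ref = TfidfTransformer(norm="l2", smooth_idf=True).fit_transform(counts)
    assert np.allclose(ours, ref.toarray(), atol=1e-10)


def _separable_data():
    pos = [Counter({"acute lbp": 1, "filler": 1}) for _ in range(10)]
    neg = [Counter({"routine visit": 1, "filler": 1}) for _ in range(10)]
    docs = pos + neg
    y = np.array([1] * 10 + [0] * 10)
    space = fit_feature_space(docs)
    return tfidf_matrix(docs, space), y, space


def test_lasso_perfect_fit_on_separable_data():
    X, y, space = _separable_data()
    model = train_lasso_lr(X, y, l1_strength=100.0, seed=0, space=space)
    pred = (lr_score(model, X) >= 0.5).astype(int)
    assert np.array_equal(pred, y)
    signal = [g for g, _ in model.nonzero_ngrams()]
    assert "acute lbp" in signal


def test_lasso_strong_penalty_collapses_to_intercept():
    X, y, _ = _separable_data()
    model = train_lasso_lr(X, y, l1_strength=1e-4, seed=0)
    assert np.all(model.coefficients == 0)
    p = lr_score(model, X)
    assert np.allclose(p, p[0])


def test_lasso_single_class_error_and_determinism():
    X, y, space = _separable_data()
    with pytest.raises(ValueError):
        train_lasso_lr(X, np.ones_like(y), 1.0)
    a = train_lasso_lr(X, y, 4.0, seed=0)
    b = train_lasso_lr(X, y, 4.0, seed=0)
    assert np.array_equal(a.coefficients, b.coefficients)
    assert a.intercept == b.intercept


def test_lr_score_closed_forms_and_dimension_check():
    space_free = None
    model = train_lasso_lr(
        sparse.csr_matrix(np.array([[1.0], [0.0]])), np.array([1, 0]), 1.0
    )
    model.coefficients = np.array([2.0])
    model.intercept = 0.0
    assert lr_score(model, np.array([0.0]))[0] == pytest.approx(0.5)
    assert lr_score(model, np.array([1.0]))[0] == pytest.approx(0.880797, abs=1e-6)
    with pytest.raises(ValueError):
        lr_score(model, np.zeros((1, 3)))


def test_shipped_lexicon_is_preprocessed_ngrams():
    lex = load_lexicon()
    assert "acute lbp" in lex
    assert all(1 <= len(g.split()) <= 5 for g in lex)
    assert not any(t in DEFAULT_STOPWORDS for g in lex for t in g.split())


def test_model_recovers_planted_phrases_on_synthetic_corpus(small_corpus):
    from lbpnlp.evaluation import PreprocessedCorpus, manual_labels
    from lbpnlp.text_processing import build_vocabulary, encode_note

    pc = PreprocessedCorpus.build(small_corpus)
    vocab = build_vocabulary(list(pc.processed.values()))
    cache: dict = {}
    enc = [encode_note(pc.processed[nid], vocab, cache=cache)
           for nid in small_corpus.note_ids]
    y = manual_labels(small_corpus)
    model = L.NgramLogisticModel("bon_lr", l1_strength=64.0)
    model.fit(enc, y, seed=0)
    positive_grams = " | ".join(g for g, c in model.model.nonzero_ngrams()
                                if c > 0)
    signal_hits = sum(kw in positive_grams for kw in
                      ("acute", "lumbar", "spasm", "relaxant", "rtw",
                       "tenderness", "naproxen", "cyclobenzaprine"))
    assert signal_hits >= 3
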