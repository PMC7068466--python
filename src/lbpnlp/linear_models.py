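"""TF-IDF n-gram logistic regression with L1 (LASSO) regularization.

Two variants share the machinery: BoN-LR indexes every n-gram (n = 1..5) seen
in the training corpus; FeatEng-LR restricts the feature space to a curated
n-gram lexicon. N-grams are formed within sentences after stop-word removal,
weighted count * idf with idf(g) = ln((1+N)/(1+df(g))) + 1, and each document
vector is L2-normalized. Classification is scikit-learn's liblinear
L1-penalized logistic regression; the regularization strength is selected on
the validation split from a small grid when not fixed.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import normalize

from .text_processing import ProcessedNote, clean_and_tokenize

logger = logging.getLogger(__name__)

#: Fixed English stop-word list applied before n-gram formation.
DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)

NGRAM_SEP = " "


def extract_ngrams(
    sentences: Sequence[Sequence[str]],
    nmax: int = 5,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> Counter:
    """Count contiguous n-grams of length 1..nmax within sentences.

    Stop words are removed first; n-grams never cross sentence boundaries.
    Keys are space-joined token sequences.
    """
    counts: Counter = Counter()
    for sent in sentences:
        toks = [t for t in sent if t not in stopwords]
        L = len(toks)
        for n in range(1, nmax + 1):
            for i in range(L - n + 1):
                counts[NGRAM_SEP.join(toks[i:i + n])] += 1
    return counts


@dataclass
class NgramFeatureSpace:
    """Indexed n-grams with idf weights (optionally lexicon-restricted)."""

    ngram_to_index: dict[str, int]
    idf: np.ndarray
    n_documents: int
    lexicon: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.ngram_to_index)


def fit_feature_space(
    corpus_counts: Sequence[Counter],
    lexicon: Iterable[str] | None = None,
) -> NgramFeatureSpace:
    """Index corpus n-grams (intersected with a lexicon in FeatEng mode).

    idf(g) = ln((1+N)/(1+df(g))) + 1 with N documents and document frequency
    df; the smoothing keeps idf finite and >= 1 for observed n-grams.
    """
    if not corpus_counts:
        raise ValueError("corpus must be non-empty")
    lex = frozenset(lexicon) if lexicon is not None else None
    df: Counter = Counter()
    for counts in corpus_counts:
        for g in counts:
            if lex is None or g in lex:
                df[g] += 1
    if not df:
        raise ValueError(
            "no lexicon n-gram occurs in the corpus" if lex is not None
            else "corpus yields no n-grams"
        )
    grams = sorted(df)
    ngram_to_index = {g: i for i, g in enumerate(grams)}
    N = len(corpus_counts)
    idf = np.array([math.log((1 + N) / (1 + df[g])) + 1 for g in grams])
    return NgramFeatureSpace(ngram_to_index=ngram_to_index, idf=idf,
                             n_documents=N, lexicon=lex)


def tfidf_vector(counts: Counter, space: NgramFeatureSpace) -> sparse.csr_matrix:
    """One document's L2-normalized count*idf vector (unseen n-grams ignored)."""
    return tfidf_matrix([counts], space)


def tfidf_matrix(
    docs_counts: Sequence[Counter], space: NgramFeatureSpace
) -> sparse.csr_matrix:
    """Stacked L2-normalized TF-IDF vectors for many documents."""
    rows, cols, vals = [], [], []
    for i, counts in enumerate(docs_counts):
        for g, c in counts.items():
            j = space.ngram_to_index.get(g)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c * space.idf[j])
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs_counts), len(space))
    )
    return normalize(X, norm="l2", copy=False)


@dataclass
class LinearModel:
    """Sparse logistic-regression coefficients over an n-gram feature space."""

    coefficients: np.ndarray
    intercept: float
    l1_strength: float
    space: NgramFeatureSpace

    def nonzero_ngrams(self) -> list[tuple[str, float]]:
        """(n-gram, coefficient) pairs with nonzero weight, descending."""
        grams = sorted(self.space.ngram_to_index, key=self.space.ngram_to_index.get)
        out = [(g, float(c)) for g, c in zip(grams, self.coefficients) if c != 0]
        out.sort(key=lambda t: -t[1])
        return out


def train_lasso_lr(
    X: sparse.csr_matrix,
    y: np.ndarray,
    l1_strength: float = 1.0,
    seed: int = 0,
    space: NgramFeatureSpace | None = None,
) -> LinearModel:
    """Fit L1-penalized logistic regression (liblinear).

    ``l1_strength`` is the inverse-regularization C of the solver; both
    classes must be present in ``y``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = LogisticRegression(
        C=l1_strength, l1_ratio=1.0, solver="liblinear", random_state=seed,
        max_iter=1000,
    )
    clf.fit(X, y)
    return LinearModel(
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        l1_strength=l1_strength,
        space=space if space is not None else NgramFeatureSpace({}, np.zeros(0), 0),
    )


def lr_score(model: LinearModel, x: sparse.spmatrix | np.ndarray) -> np.ndarray:
    """sigmoid(coefficients . x + intercept) for one or many documents."""
    if sparse.issparse(x):
        if x.shape[1] != model.coefficients.shape[0]:
            raise ValueError(
                f"dimension mismatch: {x.shape[1]} != {model.coefficients.shape[0]}"
            )
        logit = np.asarray(x @ model.coefficients).ravel() + model.intercept
    else:
        x = np.asarray(x)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != model.coefficients.shape[0]:
            raise ValueError(
                f"dimension mismatch: {x.shape[1]} != {model.coefficients.shape[0]}"
            )
        logit = x @ model.coefficients + model.intercept
    return 1.0 / (1.0 + np.exp(-logit))


def load_lexicon(path: str | Path | None = None) -> frozenset[str]:
    """Load a curated n-gram lexicon (one space-separated n-gram per line).

    Entries pass through the note preprocessing pipeline (including stop-word
    removal, so multi-word entries align with how corpus n-grams are formed).
    Without a path, the small illustrative lexicon shipped with the package is
    used.
    """
    if path is None:
        text = resources.files("lbpnlp.data").joinpath("feateng_lexicon.txt").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    grams: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = [t for t in clean_and_tokenize(line).tokens
                if t not in DEFAULT_STOPWORDS]
        if toks and len(toks) <= 5:
            grams.add(NGRAM_SEP.join(toks))
    return frozenset(grams)


class NgramLogisticModel:
    """Benchmark adapter: BoN-LR (lexicon=None) or FeatEng-LR (with lexicon)."""

    needs_embeddings = False

    def __init__(
        self,
        name: str = "bon_lr",
        lexicon: Iterable[str] | None = None,
        nmax: int = 5,
        stopwords: frozenset[str] = DEFAULT_STOPWORDS,
        l1_strength: float | None = None,
        l1_grid: Sequence[float] = (4.0, 16.0, 64.0),
    ) -> None:
        self.name = name
        self.lexicon = frozenset(lexicon) if lexicon is not None else None
        self.nmax = nmax
        self.stopwords = stopwords
        self.l1_strength = l1_strength
        self.l1_grid = tuple(l1_grid)
        self.model: LinearModel | None = None

    def _counts(self, notes: Sequence[ProcessedNote]) -> list[Counter]:
        return [extract_ngrams(n.sentences, self.nmax, self.stopwords) for n in notes]

    def fit(self, notes, labels, val_notes=None, val_labels=None, *,
            vocab=None, seed: int = 0, embeddings=None) -> "NgramLogisticModel":
        counts = self._counts(notes)
        space = fit_feature_space(counts, lexicon=self.lexicon)
        X = tfidf_matrix(counts, space)
        y = np.asarray(labels)
        if self.l1_strength is not None:
            self.model = train_lasso_lr(X, y, self.l1_strength, seed, space)
            return self
        # grid-select C on the validation split by AUC-ROC (fall back to the
        # middle of the grid when validation cannot discriminate)
        best: tuple[float, float] | None = None  # (auc, C)
        candidates: dict[float, LinearModel] = {}
        use_val = (
            val_notes is not None and val_labels is not None
            and len(np.unique(np.asarray(val_labels))) > 1
        )
        Xval = tfidf_matrix(self._counts(val_notes), space) if use_val else None
        for C in self.l1_grid:
            m = train_lasso_lr(X, y, C, seed, space)
            candidates[C] = m
            if use_val:
                auc = roc_auc_score(np.asarray(val_labels), lr_score(m, Xval))
                if best is None or auc > best[0]:
                    best = (auc, C)
        C = best[1] if best is not None else self.l1_grid[len(self.l1_grid) // 2]
        self.model = candidates[C]
        return self

    def score(self, notes: Sequence[ProcessedNote]) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit must be called before score")
        X = tfidf_matrix(self._counts(notes), self.model.space)
        return lr_score(self.model, X)


def save_linear_model(model: LinearModel, path: str | Path) -> None:
    """Serialize as TSV: an intercept header line then (n-gram, coefficient)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#intercept\t{model.intercept!r}\t#C\t{model.l1_strength!r}\n")
        for g, c in model.nonzero_ngrams():
            fh.write(f"{g}\t{c!r}\n")
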