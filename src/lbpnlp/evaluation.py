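"""Experimental protocol: 10-fold CV, label sources, thresholds, metrics.

Each model is evaluated with k-fold cross-validation (every note tested
exactly once); within each training portion a seeded 90/10 train/validation
split tunes the decision threshold (grid 0.1..1.0, step 0.1, best F score,
ties toward the smallest threshold). Supervised models can be trained either
on manual chart-review labels or on ICD-10 silver labels (M54.5 in the
encounter's code set); evaluation is always against manual labels. AUC-ROC
and AUC-PRC are computed threshold-free from the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

from .corpus import Corpus
from .text_processing import (
    ProcessedNote,
    build_vocabulary,
    clean_and_tokenize,
    encode_note,
)

logger = logging.getLogger(__name__)

POSITIVE_ICD_CODE = "M54.5"
THRESHOLD_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
METRIC_NAMES = ("precision", "recall", "f_score", "auc_roc", "auc_prc")


# ---------------------------------------------------------------------------
# Labels and folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelSource:
    """Where training labels come from: manual review or ICD-10 codes."""

    mode: str = "manual"  # "manual" | "icd10"
    positive_code: str = POSITIVE_ICD_CODE

    def labels(self, corpus: Corpus) -> np.ndarray:
        if self.mode == "manual":
            return manual_labels(corpus)
        if self.mode == "icd10":
            return icd10_labels(corpus, self.positive_code)
        raise ValueError(f"unknown label source mode {self.mode!r}")


def manual_labels(corpus: Corpus, strict: bool = False) -> np.ndarray:
    """Binary evaluation labels: 1 iff manually labeled acute_lbp.

    Unreviewed notes count as negatives ("other"); with ``strict`` they are
    marked -1 so callers can exclude them.
    """
    out = np.zeros(len(corpus), dtype=int)
    for i, n in enumerate(corpus):
        if n.manual_label == "acute_lbp":
            out[i] = 1
        elif strict and n.manual_label == "unreviewed":
            out[i] = -1
    return out


def icd10_labels(corpus: Corpus, positive_code: str = POSITIVE_ICD_CODE) -> np.ndarray:
    """Silver labels: 1 iff the code set contains the low-back-pain code.

    Doubling as the ICD-10 baseline "model" whose score is the label itself.
    """
    return np.array(
        [1 if positive_code in n.icd10_codes else 0 for n in corpus], dtype=int
    )


@dataclass
class FoldPlan:
    """Test-fold assignment for k-fold CV plus the validation fraction."""

    k: int
    assignments: dict[str, int]
    val_fraction: float = 0.1
    seed: int = 0

    def test_ids(self, fold: int) -> list[str]:
        return [nid for nid, f in self.assignments.items() if f == fold]

    def trainval_ids(self, fold: int) -> list[str]:
        return [nid for nid, f in self.assignments.items() if f != fold]


def make_folds(
    corpus: Corpus,
    k: int = 10,
    seed: int = 0,
    stratify: bool = True,
    val_fraction: float = 0.1,
) -> FoldPlan:
    """Random partition into k test folds (stratified by manual label).

    Fold sizes differ by at most one and every note appears in exactly one
    test fold; deterministic for a fixed seed.
    """
    if k > len(corpus):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
    ids = corpus.note_ids
    y = manual_labels(corpus)
    assignments: dict[str, int] = {}
    if stratify and len(np.unique(y)) > 1 and np.bincount(y).min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(ids)), y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(ids)))
    for fold, (_, test_idx) in enumerate(split):
        for i in test_idx:
            assignments[ids[i]] = fold
    return FoldPlan(k=k, assignments=assignments, val_fraction=val_fraction, seed=seed)


def split_train_val(
    ids: Sequence[str],
    labels: np.ndarray,
    val_fraction: float,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Seeded 90/10 train/validation split, stratified when possible."""
    strat = labels if len(np.unique(labels)) > 1 else None
    tr, va = train_test_split(
        list(ids), test_size=val_fraction, random_state=seed, stratify=strat
    )
    return list(tr), list(va)


# ---------------------------------------------------------------------------
# Thresholds and metrics
# ---------------------------------------------------------------------------

def _prf(scores: np.ndarray, labels: np.ndarray, threshold: float):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def tune_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    grid: Sequence[float] = THRESHOLD_GRID,
) -> float:
    """Grid threshold maximizing F score; ties go to the smallest threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to tune a threshold")
    best_t, best_f = None, -1.0
    for t in grid:
        _, _, f = _prf(scores, labels, t)
        if f > best_f:  # strict: ties keep the earlier (smaller) threshold
            best_f, best_t = f, float(t)
    return best_t


def compute_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
) -> dict[str, float]:
    """Precision/recall/F at the threshold plus threshold-free AUCs.

    AUC-ROC is the rank statistic with tie correction; AUC-PRC is the
    step-integrated precision-recall curve (average precision).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUCs")
    precision, recall, f = _prf(scores, labels, threshold)
    return {
        "precision": precision,
        "recall": recall,
        "f_score": f,
        "auc_roc": float(roc_auc_score(labels, scores)),
        "auc_prc": float(average_precision_score(labels, scores)),
    }


def score_distribution_report(
    scores: Sequence[float],
    labels: Sequence[int],
    bin_width: float = 0.1,
    exceedance_thresholds: Sequence[float] = (0.2, 0.5, 0.7),
) -> pd.DataFrame:
    """Per-class score histograms plus counts above fixed thresholds.

    Returns a tidy table with one row per (class, bin) and one row per
    (class, exceedance threshold); empty predictions give an empty table.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rows = []
    if len(scores) == 0:
        return pd.DataFrame(columns=["class", "kind", "edge", "count"])
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    for cls in (1, 0):
        s = scores[labels == cls]
        hist, _ = np.histogram(s, bins=edges)
        for lo, c in zip(edges[:-1], hist):
            rows.append({"class": cls, "kind": "bin", "edge": float(lo),
                         "count": int(c)})
        for t in exceedance_thresholds:
            rows.append({"class": cls, "kind": "above", "edge": float(t),
                         "count": int(np.sum(s > t))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-fold and averaged metrics for one model under one label source."""

    model_name: str
    label_source: str
    per_fold: pd.DataFrame       # fold, threshold, precision, ..., auc_prc
    predictions: pd.DataFrame    # note_id, score, label, model, fold

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].mean()) for m in METRIC_NAMES}

    @property
    def chosen_thresholds(self) -> list[float]:
        return list(self.per_fold["threshold"])


@dataclass
class PreprocessedCorpus:
    """Corpus plus cached per-note cleaned token sequences."""

    corpus: Corpus
    processed: dict[str, ProcessedNote]
    min_count: int = 5
    oov_max_distance: float = 2
    _fold_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def build(cls, corpus: Corpus, min_count: int = 5,
              oov_max_distance: float = 2, lemmatize: bool = True
              ) -> "PreprocessedCorpus":
        processed = {
            n.note_id: clean_and_tokenize(n.raw_text, n.note_id, lemmatize)
            for n in corpus
        }
        return cls(corpus, processed, min_count, oov_max_distance)


def _encode_fold(
    pc: PreprocessedCorpus, trainval_ids: Sequence[str]
) -> tuple[dict[str, ProcessedNote], "object"]:
    """Fit the fold vocabulary on the training portion and encode all notes.

    Results are cached on the PreprocessedCorpus, keyed by the training-id
    set, so benchmarks sharing a fold plan encode each fold once.
    """
    key = tuple(sorted(trainval_ids))
    if key in pc._fold_cache:
        return pc._fold_cache[key]
    vocab = build_vocabulary(
        [pc.processed[i] for i in trainval_ids], min_count=pc.min_count
    )
    cache: dict = {}
    encoded = {
        nid: encode_note(note, vocab, pc.oov_max_distance, cache)
        for nid, note in pc.processed.items()
    }
    pc._fold_cache[key] = (encoded, vocab)
    return encoded, vocab


def run_benchmark(
    corpus: Corpus | PreprocessedCorpus,
    models: Sequence[Callable[[], object]],
    label_source: LabelSource = LabelSource("manual"),
    folds: FoldPlan | None = None,
    seed: int = 0,
    embeddings_fn: Callable[[Sequence[Sequence[str]]], object] | None = None,
    shared_embeddings: object | None = None,
    positive_train_fraction: float = 1.0,
) -> list[EvaluationReport]:
    """Run the full cross-validation benchmark for a list of model factories.

    Per fold: the vocabulary is fitted on the fold's training portion and all
    notes are encoded against it; each model is trained on labels from
    ``label_source`` (the 90/10 validation split tunes its threshold) and
    scores the test fold; metrics are always computed against manual labels.
    ``positive_train_fraction`` < 1 randomly drops that share of positive
    training annotations (notes removed from training, not relabeled).
    ``shared_embeddings`` (or ``embeddings_fn`` applied to corpus tokens) is
    passed to models that request pretrained word vectors.
    """
    pc = corpus if isinstance(corpus, PreprocessedCorpus) \
        else PreprocessedCorpus.build(corpus)
    corpus = pc.corpus
    if folds is None:
        folds = make_folds(corpus, seed=seed)
    ids = corpus.note_ids
    index = {nid: i for i, nid in enumerate(ids)}
    y_eval = manual_labels(corpus)
    y_train_full = label_source.labels(corpus)

    factories = list(models)
    probe = [f() for f in factories]
    needs_emb = any(getattr(m, "needs_embeddings", False) for m in probe)
    if needs_emb and shared_embeddings is None and embeddings_fn is not None:
        shared_embeddings = embeddings_fn(
            [pc.processed[nid].tokens for nid in ids]
        )

    results: dict[str, list[dict]] = {m.name: [] for m in probe}
    preds: dict[str, list[dict]] = {m.name: [] for m in probe}
    drop_rng = np.random.default_rng(seed + 7919)

    for fold in range(folds.k):
        test_ids = folds.test_ids(fold)
        trainval_ids = folds.trainval_ids(fold)
        y_trainval = np.array([y_train_full[index[i]] for i in trainval_ids])
        train_ids, val_ids = split_train_val(
            trainval_ids, y_trainval, folds.val_fraction, seed + fold
        )
        if positive_train_fraction < 1.0:
            pos = [i for i in train_ids if y_train_full[index[i]] == 1]
            keep_n = int(round(len(pos) * positive_train_fraction))
            if keep_n == 0:
                logger.warning(
                    "fold %d: fraction %.3f leaves no positives; skipped",
                    fold, positive_train_fraction,
                )
                continue
            kept = set(drop_rng.choice(pos, size=keep_n, replace=False))
            train_ids = [i for i in train_ids
                         if y_train_full[index[i]] == 0 or i in kept]
        encoded, vocab = _encode_fold(pc, trainval_ids)
        tr_notes = [encoded[i] for i in train_ids]
        tr_y = np.array([y_train_full[index[i]] for i in train_ids])
        va_notes = [encoded[i] for i in val_ids]
        va_y = np.array([y_train_full[index[i]] for i in val_ids])
        te_notes = [encoded[i] for i in test_ids]
        te_y = np.array([y_eval[index[i]] for i in test_ids])

        for factory in factories:
            model = factory()
            model.fit(tr_notes, tr_y, va_notes, va_y, vocab=vocab,
                      seed=seed * 1000 + fold, embeddings=shared_embeddings)
            va_scores = model.score(va_notes)
            if len(np.unique(va_y)) > 1:
                threshold = tune_threshold(va_scores, va_y)
            else:
                threshold = 0.5
            te_scores = model.score(te_notes)
            metrics = compute_metrics(te_scores, te_y, threshold)
            results[model.name].append({"fold": fold, "threshold": threshold,
                                        **metrics})
            for nid, s in zip(test_ids, te_scores):
                preds[model.name].append({
                    "note_id": nid, "score": float(s),
                    "label": int(s >= threshold),
                    "model": model.name, "fold": fold,
                })
        logger.info("fold %d done (%d test notes)", fold, len(test_ids))

    reports = []
    for m in probe:
        reports.append(EvaluationReport(
            model_name=m.name,
            label_source=label_source.mode,
            per_fold=pd.DataFrame(results[m.name]),
            predictions=pd.DataFrame(preds[m.name]),
        ))
    return reports


def icd10_baseline_report(corpus: Corpus) -> EvaluationReport:
    """The ICD-10 baseline: the silver label itself used as the score."""
    scores = icd10_labels(corpus).astype(float)
    labels = manual_labels(corpus)
    metrics = compute_metrics(scores, labels, threshold=0.5)
    per_fold = pd.DataFrame([{"fold": 0, "threshold": 0.5, **metrics}])
    preds = pd.DataFrame({
        "note_id": corpus.note_ids, "score": scores,
        "label": (scores >= 0.5).astype(int),
        "model": "icd10", "fold": 0,
    })
    return EvaluationReport("icd10", "baseline", per_fold, preds)


def subsample_experiment(
    corpus: Corpus | PreprocessedCorpus,
    model_factory: Callable[[], object],
    fractions: Sequence[float],
    folds: FoldPlan | None = None,
    seed: int = 0,
    label_source: LabelSource = LabelSource("manual"),
    shared_embeddings: object | None = None,
) -> pd.DataFrame:
    """Annotation-subsampling curve: metrics per (fraction, fold) plus means.

    For each fraction, that share of positive training annotations is kept
    (the rest are removed from the training set); evaluation is unchanged.
    """
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fractions must lie in (0, 1]; got {f}")
    rows = []
    for frac in fractions:
        reports = run_benchmark(
            corpus, [model_factory], label_source=label_source, folds=folds,
            seed=seed, shared_embeddings=shared_embeddings,
            positive_train_fraction=frac,
        )
        for _, r in reports[0].per_fold.iterrows():
            rows.append({"fraction": frac, "fold": int(r["fold"]),
                         "auc_roc": r["auc_roc"], "auc_prc": r["auc_prc"]})
    df = pd.DataFrame(rows)
    means = df.groupby("fraction", as_index=False)[["auc_roc", "auc_prc"]].mean()
    means["fold"] = -1  # mean rows
    return pd.concat([df, means], ignore_index=True)
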