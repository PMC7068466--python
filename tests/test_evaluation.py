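"""Folds, labels, threshold tuning, metrics and the benchmark driver."""

import numpy as np
import pandas as pd
import pytest

import lbpnlp as L
from lbpnlp.corpus import ClinicalNote, Corpus
from lbpnlp.evaluation import (
    LabelSource,
    PreprocessedCorpus,
    THRESHOLD_GRID,
    compute_metrics,
    icd10_baseline_report,
    icd10_labels,
    make_folds,
    manual_labels,
    run_benchmark,
    score_distribution_report,
    subsample_experiment,
    tune_threshold,
)


# -- brute-force oracles -----------------------------------------------------

def brute_prf(scores, labels, threshold):
    tp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 1)
    fp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 0)
    fn = sum(1 for s, y in zip(scores, labels) if s < threshold and y == 1)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def brute_auc_roc(scores, labels):
    """Pair enumeration with tie correction."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_auc_prc(scores, labels):
    """Step integration of the precision-recall curve (average precision)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp = fp = 0
    n_pos = sum(labels)
    ap = 0.0
    prev_recall = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]] == 1
            fp += labels[order[j]] == 0
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


# -- folds and labels --------------------------------------------------------

def _mini_corpus(n=20, n_pos=6):
    notes = []
    for i in range(n):
        label = "acute_lbp" if i < n_pos else "other"
        codes = frozenset({"M54.5"}) if i % 3 == 0 else frozenset()
        notes.append(ClinicalNote(f"n{i}", f"note body text number {i} "
                                           f"with several words",
                                  manual_label=label, icd10_codes=codes))
    return Corpus(notes)


def test_folds_partition_evenly_and_deterministically():
    corpus = _mini_corpus(20)
    plan = make_folds(corpus, k=10, seed=3, stratify=False)
    sizes = [len(plan.test_ids(f)) for f in range(10)]
    assert sizes == [2] * 10
    all_ids = sorted(i for f in range(10) for i in plan.test_ids(f))
    assert all_ids == sorted(corpus.note_ids)
    again = make_folds(corpus, k=10, seed=3, stratify=False)
    assert plan.assignments == again.assignments
    with pytest.raises(ValueError):
        make_folds(corpus, k=21, seed=0)


def test_stratified_folds_balance_positives():
    corpus = _mini_corpus(40, n_pos=10)
    plan = make_folds(corpus, k=5, seed=0, stratify=True)
    y = {nid: lab for nid, lab in zip(corpus.note_ids, manual_labels(corpus))}
    per_fold_pos = [sum(y[i] for i in plan.test_ids(f)) for f in range(5)]
    assert per_fold_pos == [2] * 5


def test_icd10_labels_membership():
    notes = [
        ClinicalNote("a", "text one two", icd10_codes=frozenset({"M54.5", "E11"})),
        ClinicalNote("b", "text one two", icd10_codes=frozenset()),
    ]
    assert icd10_labels(Corpus(notes)).tolist() == [1, 0]


# -- thresholds and metrics --------------------------------------------------

def test_tune_threshold_perfect_separation_prefers_smallest():
    scores = [0.9] * 5 + [0.1] * 5
    labels = [1] * 5 + [0] * 5
    assert tune_threshold(scores, labels) == pytest.approx(0.2)


def test_tune_threshold_identical_scores_closed_form():
    scores = [0.5] * 10
    labels = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]
    t = tune_threshold(scores, labels)
    assert t == pytest.approx(0.1)  # everything predicted positive
    p = 0.2
    _, _, f = brute_prf(scores, labels, t)
    assert f == pytest.approx(2 * p / (p + 1))


def test_tune_threshold_degenerate_grid():
    assert tune_threshold([0.9, 0.1], [1, 0], grid=[1.0]) == 1.0


def test_compute_metrics_perfect_and_derived_example():
    m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5)
    assert all(m[k] == pytest.approx(1.0) for k in m)
    m2 = compute_metrics([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0], 0.5)
    assert m2["precision"] == pytest.approx(0.5)
    assert m2["recall"] == pytest.approx(0.5)
    assert m2["f_score"] == pytest.approx(0.5)
    assert m2["auc_roc"] == pytest.approx(0.75)
    with pytest.raises(ValueError):
        compute_metrics([0.5, 0.6], [1, 1], 0.5)


def test_metrics_match_bruteforce_oracles_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(4, 31))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        t = float(rng.choice(THRESHOLD_GRID))
        m = compute_metrics(scores, labels, t)
        p, r, f = brute_prf(scores, labels, t)
        assert m["precision"] == pytest.approx(p, abs=1e-9)
        assert m["recall"] == pytest.approx(r, abs=1e-9)
        assert m["f_score"] == pytest.approx(f, abs=1e-9)
        assert m["auc_roc"] == pytest.approx(
            brute_auc_roc(scores, labels), abs=1e-9)
        assert m["auc_prc"] == pytest.approx(
            brute_auc_prc(scores.tolist(), labels.tolist()), abs=1e-9)


def test_score_distribution_report_counts_and_monotonicity():
    rep = score_distribution_report([0.9, 0.9, 0.3], [1, 1, 0])
    above_pos = rep[(rep["class"] == 1) & (rep["kind"] == "above")]
    counts = dict(zip(above_pos["edge"], above_pos["count"]))
    assert counts[0.2] == 2 and counts[0.5] == 2 and counts[0.7] == 2
    assert counts[0.2] >= counts[0.5] >= counts[0.7]
    assert score_distribution_report([], []).empty


# -- benchmark driver --------------------------------------------------------

@pytest.fixture(scope="module")
def quick_benchmark():
    corpus = L.generate_corpus(L.SyntheticConfig(n_notes=200, seed=11,
                                                 positive_rate=0.15))
    pc = PreprocessedCorpus.build(corpus)
    folds = make_folds(corpus, k=3, seed=11)
    reports = run_benchmark(
        pc, [lambda: L.WordSearchModel(),
             lambda: L.NgramLogisticModel("bon_lr", l1_strength=16.0)],
        LabelSource("manual"), folds, seed=11,
    )
    return corpus, pc, folds, reports


def test_benchmark_scores_every_note_exactly_once(quick_benchmark):
    corpus, _, _, reports = quick_benchmark
    for rep in reports:
        assert sorted(rep.predictions["note_id"]) == sorted(corpus.note_ids)


def test_benchmark_f_is_harmonic_mean_per_fold(quick_benchmark):
    _, _, _, reports = quick_benchmark
    for rep in reports:
        for _, row in rep.per_fold.iterrows():
            p, r = row["precision"], row["recall"]
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert row["f_score"] == pytest.approx(expected)
        assert set(rep.per_fold.columns) >= {"precision", "recall", "f_score",
                                             "auc_roc", "auc_prc", "threshold"}


def test_benchmark_is_reproducible(quick_benchmark):
    corpus, _, folds, reports = quick_benchmark
    pc2 = PreprocessedCorpus.build(corpus)
    again = run_benchmark(
        pc2, [lambda: L.WordSearchModel(),
              lambda: L.NgramLogisticModel("bon_lr", l1_strength=16.0)],
        LabelSource("manual"), folds, seed=11,
    )
    for a, b in zip(reports, again):
        pd.testing.assert_frame_equal(a.per_fold, b.per_fold)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)


def test_icd_baseline_reproduces_configured_discordance():
    corpus = L.generate_corpus(L.SyntheticConfig(n_notes=1500, seed=5))
    rep = icd10_baseline_report(corpus)
    # binomial sampling noise at ~75 positives: allow a generous band
    assert rep.mean["precision"] == pytest.approx(0.32, abs=0.12)
    assert rep.mean["recall"] == pytest.approx(0.68, abs=0.15)


def test_subsample_fraction_one_matches_benchmark(quick_benchmark):
    corpus, pc, folds, reports = quick_benchmark
    df = subsample_experiment(
        pc, lambda: L.NgramLogisticModel("bon_lr", l1_strength=16.0),
        fractions=[1.0], folds=folds, seed=11,
    )
    folds_rows = df[df["fold"] >= 0]
    assert len(folds_rows) == folds.k
    bon = [r for r in reports if r.model_name == "bon_lr"][0]
    assert folds_rows["auc_roc"].tolist() == bon.per_fold["auc_roc"].tolist()


def test_subsample_validates_fractions(quick_benchmark):
    _, pc, folds, _ = quick_benchmark
    with pytest.raises(ValueError):
        subsample_experiment(pc, lambda: L.WordSearchModel(), [0.0],
                             folds=folds)
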