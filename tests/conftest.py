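"""Shared fixtures.

The expensive session-scoped fixtures generate one synthetic study corpus
(n = 2000, 5% prevalence, half the positives expressing acuity only by
paraphrase) and run the cross-validated benchmarks once; several tests read
different aspects of the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

import lbpnlp as L
from lbpnlp.evaluation import (
    LabelSource,
    PreprocessedCorpus,
    make_folds,
    run_benchmark,
)

STUDY_SEED = 42


@pytest.fixture()
def tiny_corpus() -> L.Corpus:
    notes = [
        L.ClinicalNote("n1", "Patient presents with acute low back pain after "
                             "lifting. Prescribed muscle relaxant.",
                       encounter_id="e1", icd10_codes=frozenset({"M54.5"}),
                       manual_label="acute_lbp", timestamp="2017-01-02T09:00:00"),
        L.ClinicalNote("n2", "Annual physical. Denies acute lbp. Labs reviewed.",
                       encounter_id="e2", manual_label="other",
                       timestamp="2017-01-03T09:00:00"),
        L.ClinicalNote("n3", "Followup for chronic low back pain, stable.",
                       encounter_id="e3", icd10_codes=frozenset({"M54.5"}),
                       manual_label="other", timestamp="2017-01-04T09:00:00"),
    ]
    return L.Corpus(notes=notes, provenance="tiny fixture")


@pytest.fixture(scope="session")
def small_corpus() -> L.Corpus:
    """A quick 300-note synthetic corpus for unit-level pipeline tests."""
    return L.generate_corpus(L.SyntheticConfig(n_notes=300, seed=7))


@pytest.fixture(scope="session")
def study_corpus() -> L.Corpus:
    """The study-condition corpus: n=2000, 5% positives, paraphrase rate 0.5."""
    cfg = L.SyntheticConfig(n_notes=2000, paraphrase_rate=0.5, seed=STUDY_SEED)
    return L.generate_corpus(cfg)


@pytest.fixture(scope="session")
def study_setup(study_corpus):
    """Preprocessed corpus, fold plan and shared skip-gram embeddings."""
    pc = PreprocessedCorpus.build(study_corpus)
    folds = make_folds(study_corpus, k=10, seed=STUDY_SEED)
    emb = L.pretrain_embeddings(
        [pc.processed[nid].tokens for nid in study_corpus.note_ids],
        dim=32, seed=STUDY_SEED,
    )
    return {"corpus": study_corpus, "pc": pc, "folds": folds, "embeddings": emb}


def _factories(lexicon):
    return [
        lambda: L.WordSearchModel(),
        lambda: L.TopicModelScorer(K=40, top_m=2),
        lambda: L.NgramLogisticModel("bon_lr"),
        lambda: L.NgramLogisticModel("feateng_lr", lexicon=lexicon),
        lambda: L.ConvNetModel(L.ConvNetConfig.scaled()),
    ]


@pytest.fixture(scope="session")
def manual_benchmark(study_setup):
    """10-fold CV of all five models trained on manual labels."""
    reports = run_benchmark(
        study_setup["pc"], _factories(L.load_lexicon()),
        LabelSource("manual"), study_setup["folds"], seed=STUDY_SEED,
        shared_embeddings=study_setup["embeddings"],
    )
    return {r.model_name: r for r in reports}


@pytest.fixture(scope="session")
def icd_benchmark(study_setup):
    """10-fold CV of the supervised models trained on ICD-10 silver labels."""
    lexicon = L.load_lexicon()
    factories = [
        lambda: L.NgramLogisticModel("bon_lr"),
        lambda: L.NgramLogisticModel("feateng_lr", lexicon=lexicon),
        lambda: L.ConvNetModel(L.ConvNetConfig.scaled()),
    ]
    reports = run_benchmark(
        study_setup["pc"], factories,
        LabelSource("icd10"), study_setup["folds"], seed=STUDY_SEED,
        shared_embeddings=study_setup["embeddings"],
    )
    return {r.model_name: r for r in reports}


@pytest.fixture(scope="session")
def trained_convnet(study_setup):
    """One ConvNet trained on a single fold's training split (for attribution)."""
    corpus = study_setup["corpus"]
    pc = study_setup["pc"]
    folds = study_setup["folds"]
    from lbpnlp.evaluation import manual_labels, split_train_val, _encode_fold

    y = manual_labels(corpus)
    index = {nid: i for i, nid in enumerate(corpus.note_ids)}
    trainval = folds.trainval_ids(0)
    tr, va = split_train_val(
        trainval, np.array([y[index[i]] for i in trainval]), 0.1, STUDY_SEED
    )
    encoded, vocab = _encode_fold(pc, trainval)
    model = L.ConvNetModel(L.ConvNetConfig.scaled())
    model.fit(
        [encoded[i] for i in tr], np.array([y[index[i]] for i in tr]),
        [encoded[i] for i in va], np.array([y[index[i]] for i in va]),
        vocab=vocab, seed=STUDY_SEED,
        embeddings=study_setup["embeddings"],
    )
    test_notes = [encoded[i] for i in folds.test_ids(0)]
    test_y = np.array([y[index[i]] for i in folds.test_ids(0)])
    return {"model": model, "test_notes": test_notes, "test_y": test_y,
            "vocab": vocab}
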