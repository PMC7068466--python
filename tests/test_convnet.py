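"""Skip-gram embeddings, ConvNet forward/training and n-gram attribution."""

import numpy as np
import pytest

import lbpnlp as L
from lbpnlp.convnet import (
    AttributionRecord,
    ConvNetClassifier,
    ConvNetConfig,
    EmbeddingMatrix,
    attribute_ngrams,
    pretrain_embeddings,
)
from lbpnlp.text_processing import ProcessedNote


def _cos(emb, a, b):
    va, vb = emb.get(a), emb.get(b)
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


@pytest.fixture(scope="module")
def cooccurrence_embeddings():
    """Corpus where two drug names share contexts; a third word does not."""
    rng = np.random.default_rng(5)
    docs = []
    for _ in range(300):
        drug = "flexeril" if rng.random() < 0.5 else "cyclobenzaprine"
        docs.append(["prescribed", drug, "for", "muscle", "spasm"])
        docs.append(["thyroid", "panel", "within", "normal", "limits"])
    return pretrain_embeddings(docs, dim=16, seed=0, epochs=5)


def test_skipgram_places_shared_context_words_closer(cooccurrence_embeddings):
    emb = cooccurrence_embeddings
    assert _cos(emb, "flexeril", "cyclobenzaprine") > _cos(
        emb, "flexeril", "thyroid")


def test_skipgram_shapes_and_padding_row(cooccurrence_embeddings):
    emb = cooccurrence_embeddings
    assert emb.vectors.shape == (len(emb.terms) + 1, 16)
    assert np.all(emb.vectors[0] == 0.0)


def test_skipgram_deterministic_for_fixed_seed():
    docs = [["a", "b", "c", "d"] * 5, ["c", "d", "e", "f"] * 5]
    e1 = pretrain_embeddings(docs, dim=8, seed=3, epochs=2, sample=0)
    e2 = pretrain_embeddings(docs, dim=8, seed=3, epochs=2, sample=0)
    assert np.array_equal(e1.vectors, e2.vectors)


def test_pooled_vector_length_is_kernels_times_filters():
    terms = [f"t{i}" for i in range(6)]
    for d, expected in ((2, 10), (200, 1000)):
        cfg = ConvNetConfig(embed_dim=4, filters_per_kernel=d, fc_sizes=(8, 8))
        assert cfg.pooled_dim == expected
        clf = ConvNetClassifier(cfg, terms)
        X = np.array([[1, 2, 3, 4, 5, 0, 0]])
        _, cache = clf.forward(X)
        assert cache["pooled"].shape == (1, expected)


def test_forward_score_in_unit_interval_and_short_note_padding():
    cfg = ConvNetConfig(embed_dim=4, filters_per_kernel=3, fc_sizes=(6, 6))
    clf = ConvNetClassifier(cfg, ["a", "b"])
    ids = clf.encode_tokens(["a"])
    assert len(ids) == 5  # padded to the largest kernel
    p = clf.score_tokens([["a"], [], ["a", "b", "a", "b", "a", "b"]])
    assert np.all((p > 0) & (p < 1))


def test_maxpool_translation_invariance_under_padding():
    """Shifting a phrase within zero padding leaves pooled activations fixed."""
    cfg = ConvNetConfig(embed_dim=4, filters_per_kernel=3, fc_sizes=(6, 6),
                        seed=1)
    clf = ConvNetClassifier(cfg, ["a", "b", "c"])
    left = np.array([[1, 2, 3, 0, 0, 0, 0]])
    right = np.array([[0, 0, 0, 0, 1, 2, 3]])
    _, cl = clf.forward(left)
    _, cr = clf.forward(right)
    # kernel-1..3 units that fire on the phrase itself must agree
    for k in (1, 2, 3):
        hl = np.maximum(cl["conv"][k][0], 0)
        hr = np.maximum(cr["conv"][k][0], 0)
        assert np.allclose(hl.max(), hr.max())


def _toy_corpus(n=500, seed=0):
    rng = np.random.default_rng(seed)
    notes, labels = [], []
    background = ["visit", "exam", "labs", "stable", "followup", "normal"]
    for i in range(n):
        toks = list(rng.choice(background, size=12))
        label = int(rng.random() < 0.3)
        if label:
            pos = int(rng.integers(0, len(toks) - 1))
            toks[pos:pos] = ["acute", "lbp"]
        notes.append(toks)
        labels.append(label)
    return notes, np.array(labels)


def test_training_separates_planted_phrase_and_null_is_chance():
    """Planted-phrase data is learned within the 5-epoch schedule; shuffled
    labels give near-chance ranking.

    The toy run disables dropout and raises the step size: at a few hundred
    optimizer steps regularization noise dominates otherwise.
    """
    notes, y = _toy_corpus()
    vocab_terms = sorted({t for n in notes for t in n})
    cfg = ConvNetConfig(embed_dim=8, filters_per_kernel=32, fc_sizes=(32, 32),
                        dropout=0.0, lr=0.003, seed=0)
    clf = ConvNetClassifier(cfg, vocab_terms)
    clf.fit(notes[:400], y[:400])
    from sklearn.metrics import roc_auc_score
    auc = roc_auc_score(y[400:], clf.score_tokens(notes[400:]))
    assert auc >= 0.95

    rng = np.random.default_rng(1)
    y_shuffled = rng.permutation(y[:400])
    clf0 = ConvNetClassifier(cfg, vocab_terms)
    clf0.fit(notes[:400], y_shuffled)
    auc0 = roc_auc_score(y[400:], clf0.score_tokens(notes[400:]))
    assert abs(auc0 - 0.5) <= 0.25


def test_training_is_deterministic_for_fixed_seed():
    notes, y = _toy_corpus(n=120)
    vocab_terms = sorted({t for n in notes for t in n})
    cfg = ConvNetConfig(embed_dim=6, filters_per_kernel=4, fc_sizes=(8, 8),
                        epochs=2, seed=9)
    runs = []
    for _ in range(2):
        clf = ConvNetClassifier(cfg, vocab_terms)
        clf.fit(notes[:100], y[:100], notes[100:], y[100:])
        runs.append((clf.history[-1]["val_loss"], clf.p["w_out"].copy()))
    assert runs[0][0] == runs[1][0]
    assert np.array_equal(runs[0][1], runs[1][1])


def _single_path_network():
    """One kernel-2 filter hand-wired to fire only on 'acute lbp'."""
    cfg = ConvNetConfig(embed_dim=2, kernel_sizes=(2,), filters_per_kernel=1,
                        fc_sizes=(1, 1), dropout=0.0, seed=0)
    clf = ConvNetClassifier(cfg, ["acute", "lbp", "visit", "exam"])
    emb = np.zeros((5, 2))
    emb[1] = [1.0, 0.0]   # acute
    emb[2] = [0.0, 1.0]   # lbp
    emb[3] = [-1.0, -1.0]  # visit
    emb[4] = [-1.0, -1.0]  # exam
    clf.p["emb"] = emb
    clf.p["W2"] = np.array([[1.0], [0.0], [0.0], [1.0]])  # detects acute->lbp
    clf.p["b2"] = np.array([-1.5])  # only the exact bigram clears the bias
    for i in range(2):
        clf.p[f"Wfc{i}"] = np.array([[1.0]])
        clf.p[f"bfc{i}"] = np.zeros(1)
        clf.p[f"gamma{i}"] = np.ones(1)
        clf.p[f"beta{i}"] = np.zeros(1)
        clf.running[f"mean{i}"] = np.zeros(1)
        clf.running[f"var{i}"] = np.ones(1)
    clf.p["w_out"] = np.array([2.0])
    clf.p["b_out"] = np.array([-1.0])
    return clf


def test_attribution_single_path_network_ranks_trigger_first():
    clf = _single_path_network()
    records = attribute_ngrams(clf, ["visit", "acute", "lbp", "exam"], "n1")
    assert records
    assert records[0].ngram == ("acute", "lbp")
    assert records[0].contribution > 0
    # without the trigger bigram no unit fires and nothing is attributed
    assert attribute_ngrams(clf, ["visit", "exam", "visit", "exam"]) == []


def test_attribution_sums_approximate_total_logit_shift():
    """Unit-wise occlusions vs occluding every pooled unit at once.

    On a three-filter toy network whose hidden units stay active over the
    occlusion range the head is affine, so summed per-unit log-odds shifts
    must track the total shift closely.
    """
    cfg = ConvNetConfig(embed_dim=2, kernel_sizes=(1, 2, 3),
                        filters_per_kernel=1, fc_sizes=(3, 3), dropout=0.0,
                        seed=2)
    clf = ConvNetClassifier(cfg, ["a", "b", "c", "d"])
    emb = np.zeros((5, 2))
    emb[1:] = [[1.0, 0.2], [0.3, 1.0], [0.8, 0.8], [0.2, 0.4]]
    clf.p["emb"] = emb
    for k in (1, 2, 3):
        clf.p[f"W{k}"] = np.abs(clf.p[f"W{k}"])
        clf.p[f"b{k}"] = np.full(1, 0.1)
    for i in range(2):
        clf.p[f"Wfc{i}"] = np.eye(3)
        clf.p[f"bfc{i}"] = np.full(3, 0.5)  # keeps ReLUs active when occluded
        clf.running[f"mean{i}"] = np.zeros(3)
        clf.running[f"var{i}"] = np.ones(3)
    clf.p["w_out"] = np.array([0.7, 0.5, 0.3])
    clf.p["b_out"] = np.array([-0.4])
    tokens = ["a", "b", "c", "d", "a", "b"]
    X = clf.encode_tokens(tokens)[None, :]
    prob, cache = clf.forward(X)
    pooled = cache["pooled"].copy()
    base_logit = np.log(prob[0] / (1 - prob[0]))
    p_zeroed, _ = clf._head(np.zeros_like(pooled), train=False)
    total_shift = base_logit - np.log(p_zeroed[0] / (1 - p_zeroed[0]))
    records = attribute_ngrams(clf, tokens)
    summed = sum(r.contribution for r in records)
    assert abs(total_shift) > 0.1  # the toy path is not degenerate
    assert abs(summed - total_shift) <= 0.25 * abs(total_shift)


def test_checkpoint_round_trip(tmp_path):
    from lbpnlp.convnet import load_checkpoint, save_checkpoint

    notes, y = _toy_corpus(n=80)
    vocab_terms = sorted({t for n in notes for t in n})
    cfg = ConvNetConfig(embed_dim=6, filters_per_kernel=4, fc_sizes=(8, 8),
                        epochs=1, seed=4)
    clf = ConvNetClassifier(cfg, vocab_terms)
    clf.fit(notes, y)
    path = tmp_path / "model.npz"
    save_checkpoint(clf, path)
    loaded = load_checkpoint(path)
    assert loaded.config == clf.config
    assert np.array_equal(loaded.score_tokens(notes[:10]),
                          clf.score_tokens(notes[:10]))


def test_convnet_model_adapter_round_trip(small_corpus):
    from lbpnlp.evaluation import PreprocessedCorpus, manual_labels
    from lbpnlp.text_processing import build_vocabulary, encode_note

    pc = PreprocessedCorpus.build(small_corpus)
    vocab = build_vocabulary(list(pc.processed.values()))
    cache: dict = {}
    enc = [encode_note(pc.processed[nid], vocab, cache=cache)
           for nid in small_corpus.note_ids]
    y = manual_labels(small_corpus)
    cfg = ConvNetConfig(embed_dim=8, filters_per_kernel=4, fc_sizes=(8, 8),
                        epochs=1)
    model = L.ConvNetModel(cfg, pretrain=False)
    model.fit(enc[:250], y[:250], enc[250:], y[250:], vocab=vocab, seed=0)
    scores = model.score(enc[250:])
    assert scores.shape == (50,)
    assert np.all((scores > 0) & (scores < 1))
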