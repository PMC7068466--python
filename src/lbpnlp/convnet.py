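"""ConvNet: multi-kernel convolutional text classifier with n-gram attribution.

Architecture: word embeddings (pretrained with skip-gram word2vec on the note
corpus, fine-tuned during supervised training) feed parallel 1-D convolutions
with kernel sizes 1..5 (emulating n-grams with n = 1..5), each ReLU-activated
and global-max-pooled over the whole sequence; the pooled activations are
concatenated (length |kernels| x filters), passed through two fully connected
layers with batch normalization and ReLU, and a sigmoid output gives the
acute-LBP probability. Training uses binary cross-entropy with Adam for a
fixed number of epochs (no early stopping). Dropout is applied to the pooled
concatenation and after each fully connected layer.

Attribution: each max-pool unit is produced by one input window (an n-gram of
that kernel's size); a unit's contribution is the log-odds change when its
pooled activation is occluded (set to zero), and contributions are summed per
distinct n-gram.

Everything here is a compact vectorized numpy implementation (batched matmul
convolutions via stacked shifted views, manual backprop, Adam, batch norm).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .text_processing import ProcessedNote, Vocabulary

logger = logging.getLogger(__name__)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Skip-gram (word2vec) embedding pretraining
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingMatrix:
    """Per-term embedding vectors plus an all-zero padding row (row 0)."""

    terms: tuple[str, ...]
    vectors: np.ndarray  # (len(terms) + 1, dim); row 0 is the frozen pad
    term_to_row: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.terms) + 1:
            raise ValueError("vectors must have one row per term plus padding")
        if not self.term_to_row:
            self.term_to_row = {t: i + 1 for i, t in enumerate(self.terms)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def get(self, term: str) -> np.ndarray | None:
        i = self.term_to_row.get(term)
        return None if i is None else self.vectors[i]


def pretrain_embeddings(
    corpus_tokens: Sequence[Sequence[str]],
    dim: int = 300,
    seed: int = 0,
    window: int = 5,
    negative: int = 5,
    epochs: int = 5,
    lr: float = 0.025,
    batch_pairs: int = 1024,
    min_count: int = 1,
    sample: float = 1e-3,
) -> EmbeddingMatrix:
    """Train skip-gram-with-negative-sampling embeddings on the corpus.

    ``corpus_tokens`` is a list of token lists (one per note). Defaults follow
    the common word2vec convention: dynamic window up to 5, 5 negative samples
    drawn from the unigram^0.75 distribution, frequent-word subsampling at
    threshold ``sample``, 5 epochs, linearly decaying learning rate.
    Deterministic for a fixed seed.
    """
    if not corpus_tokens:
        raise ValueError("corpus must be non-empty")
    rng = np.random.default_rng(seed)
    freq: Counter = Counter()
    for toks in corpus_tokens:
        freq.update(toks)
    terms = [t for t, c in freq.items() if c >= min_count]
    terms.sort(key=lambda t: (-freq[t], t))
    row = {t: i + 1 for i, t in enumerate(terms)}  # 0 = pad, never sampled
    V = len(terms)
    if V == 0:
        raise ValueError("no term reaches min_count")
    w_in = (rng.random((V + 1, dim)) - 0.5) / dim
    w_out = np.zeros((V + 1, dim))
    w_in[0] = 0.0

    # frequent-word subsampling keep-probabilities (word2vec convention)
    total = sum(freq[t] for t in terms)
    keep = np.ones(V + 1)
    if sample > 0:
        for t, i in row.items():
            z = freq[t] / total
            if z > sample:
                keep[i] = min(1.0, (np.sqrt(z / sample) + 1) * sample / z)

    # skip-gram pairs with per-center dynamic window
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for toks in corpus_tokens:
        ids = np.array([row[t] for t in toks if t in row], dtype=np.int64)
        if sample > 0 and len(ids):
            ids = ids[rng.random(len(ids)) < keep[ids]]
        n = len(ids)
        if n < 2:
            continue
        b = rng.integers(1, window + 1, size=n)
        for i in range(n):
            lo, hi = max(0, i - b[i]), min(n, i + b[i] + 1)
            ctx = np.concatenate([ids[lo:i], ids[i + 1:hi]])
            centers.append(np.full(len(ctx), ids[i]))
            contexts.append(ctx)
    if not centers:
        logger.warning("no skip-gram pairs survive subsampling; "
                       "returning initial embeddings")
        return EmbeddingMatrix(terms=tuple(terms), vectors=w_in)
    ci = np.concatenate(centers)
    oi = np.concatenate(contexts)
    n_pairs = len(ci)

    # unigram^0.75 negative-sampling distribution (over real terms only)
    counts = np.array([freq[t] for t in terms], dtype=float) ** 0.75
    neg_cdf = np.cumsum(counts / counts.sum())

    total_batches = max(1, epochs * ((n_pairs + batch_pairs - 1) // batch_pairs))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch_pairs):
            idx = order[s:s + batch_pairs]
            c, o = ci[idx], oi[idx]
            B = len(c)
            ni = np.searchsorted(neg_cdf, rng.random((B, negative))) + 1
            alpha = lr * max(1e-4, 1.0 - step / total_batches)
            step += 1
            vc = w_in[c]                       # (B, d)
            vo = w_out[o]                      # (B, d)
            vn = w_out[ni]                     # (B, neg, d)
            gpos = _sigmoid((vc * vo).sum(1)) - 1.0         # (B,)
            gneg = _sigmoid(np.einsum("bnd,bd->bn", vn, vc))  # (B, neg)
            dvc = gpos[:, None] * vo + np.einsum("bn,bnd->bd", gneg, vn)
            np.add.at(w_in, c, -alpha * dvc)
            np.add.at(w_out, o, -alpha * gpos[:, None] * vc)
            np.add.at(
                w_out, ni.ravel(),
                (-alpha * gneg[..., None] * vc[:, None, :]).reshape(-1, dim),
            )
            w_in[0] = 0.0
    return EmbeddingMatrix(terms=tuple(terms), vectors=w_in)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class ConvNetConfig:
    """Hyperparameters; defaults match the full-scale configuration."""

    embed_dim: int = 300
    kernel_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
    filters_per_kernel: int = 200
    fc_sizes: tuple[int, int] = (600, 600)
    dropout: float = 0.5
    lr: float = 0.001
    epochs: int = 5
    batch_size: int = 32
    seed: int = 0

    @property
    def pooled_dim(self) -> int:
        return len(self.kernel_sizes) * self.filters_per_kernel

    @classmethod
    def scaled(cls, seed: int = 0) -> "ConvNetConfig":
        """Desk-scale preset for experiments on small synthetic corpora.

        Keeps the architecture shape, epoch/batch schedule and dropout, with
        reduced widths (embedding 32, 32 filters per kernel, two FC layers
        of 64) sized for corpora of a few thousand short notes. The step
        size is raised to 0.003: a few-thousand-note corpus provides an
        order of magnitude fewer optimizer steps than the full-scale
        schedule assumes, and at lr 0.001 the scores stay compressed near
        the class prior.
        """
        return cls(embed_dim=32, filters_per_kernel=32, fc_sizes=(64, 64),
                   lr=0.003, seed=seed)


class ConvNetClassifier:
    """The network itself: parameters, forward/backward, Adam training."""

    def __init__(
        self,
        config: ConvNetConfig,
        vocab_terms: Sequence[str],
        pretrained: EmbeddingMatrix | None = None,
    ) -> None:
        self.config = config
        self.terms = tuple(vocab_terms)
        self.term_to_id = {t: i + 1 for i, t in enumerate(self.terms)}
        rng = np.random.default_rng(config.seed)
        V, E = len(self.terms), config.embed_dim
        emb = rng.normal(0, 0.1, size=(V + 1, E))
        if pretrained is not None:
            if pretrained.dim != E:
                raise ValueError(
                    f"pretrained dim {pretrained.dim} != embed_dim {E}"
                )
            for t, i in self.term_to_id.items():
                vec = pretrained.get(t)
                if vec is not None:
                    emb[i] = vec
        emb[0] = 0.0  # frozen padding row
        self.p: dict[str, np.ndarray] = {"emb": emb}
        F = config.filters_per_kernel
        for k in config.kernel_sizes:
            fan_in = k * E
            self.p[f"W{k}"] = rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, F))
            self.p[f"b{k}"] = np.zeros(F)
        dims = [config.pooled_dim, *config.fc_sizes]
        for i in range(2):
            self.p[f"Wfc{i}"] = rng.normal(
                0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1])
            )
            self.p[f"bfc{i}"] = np.zeros(dims[i + 1])
            self.p[f"gamma{i}"] = np.ones(dims[i + 1])
            self.p[f"beta{i}"] = np.zeros(dims[i + 1])
        self.p["w_out"] = rng.normal(0, np.sqrt(1.0 / dims[2]), size=dims[2])
        self.p["b_out"] = np.zeros(1)
        self.running: dict[str, np.ndarray] = {
            f"{s}{i}": (np.zeros(dims[i + 1]) if s == "mean" else np.ones(dims[i + 1]))
            for i in range(2) for s in ("mean", "var")
        }
        self.bn_momentum = 0.1
        self.bn_eps = 1e-5
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0
        self._train_rng = np.random.default_rng(config.seed + 1)
        self.history: list[dict[str, float]] = []

    # -- encoding -----------------------------------------------------------

    def encode_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        """Map tokens to integer ids; unknown tokens are dropped.

        Empty or too-short notes are padded up to the largest kernel size.
        """
        ids = [self.term_to_id[t] for t in tokens if t in self.term_to_id]
        kmax = max(self.config.kernel_sizes)
        if len(ids) == 0:
            logger.warning("note has no in-vocabulary tokens; scoring all-padding")
        if len(ids) < kmax:
            ids = ids + [0] * (kmax - len(ids))
        return np.array(ids, dtype=np.int64)

    # -- forward ------------------------------------------------------------

    def _conv_pool(self, E_: np.ndarray, X: np.ndarray, k: int):
        """Convolution + ReLU + global max-pool for one kernel size."""
        B, L, E = E_.shape
        P = L - k + 1
        win = np.concatenate(
            [E_[:, i:P + i, :] for i in range(k)], axis=2
        )  # (B, P, k*E)
        z = win @ self.p[f"W{k}"] + self.p[f"b{k}"]  # (B, P, F)
        pos = z.argmax(axis=1)                        # (B, F)
        zmax = np.take_along_axis(z, pos[:, None, :], axis=1)[:, 0, :]
        h = np.maximum(zmax, 0.0)
        return h, zmax, pos, win

    def _bn(self, a: np.ndarray, i: int, train: bool):
        if train:
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            m = self.bn_momentum
            self.running[f"mean{i}"] = (1 - m) * self.running[f"mean{i}"] + m * mu
            n = max(a.shape[0], 2)
            self.running[f"var{i}"] = (
                (1 - m) * self.running[f"var{i}"] + m * var * n / (n - 1)
            )
        else:
            mu, var = self.running[f"mean{i}"], self.running[f"var{i}"]
        inv = 1.0 / np.sqrt(var + self.bn_eps)
        xhat = (a - mu) * inv
        return self.p[f"gamma{i}"] * xhat + self.p[f"beta{i}"], xhat, inv

    def _head(self, pooled: np.ndarray, train: bool, rng=None):
        """FC(600)+BN+ReLU x2 -> sigmoid, from the pooled concatenation."""
        cache: dict = {"pooled": pooled}
        x = pooled
        drop = self.config.dropout
        for i in range(2):
            if train and drop > 0:
                mask = (rng.random(x.shape) >= drop) / (1 - drop)
                x = x * mask
                cache[f"mask{i}"] = mask
            a = x @ self.p[f"Wfc{i}"] + self.p[f"bfc{i}"]
            bn, xhat, inv = self._bn(a, i, train)
            r = np.maximum(bn, 0.0)
            cache[f"x{i}"], cache[f"bn{i}"] = x, bn
            cache[f"xhat{i}"], cache[f"inv{i}"], cache[f"r{i}"] = xhat, inv, r
            x = r
        if train and drop > 0:
            mask = (rng.random(x.shape) >= drop) / (1 - drop)
            x = x * mask
            cache["mask_out"] = mask
        cache["x_out"] = x
        logit = x @ self.p["w_out"] + self.p["b_out"][0]
        cache["logit"] = logit
        return _sigmoid(logit), cache

    def forward(
        self, X: np.ndarray, train: bool = False, rng=None
    ) -> tuple[np.ndarray, dict]:
        """Score a padded id batch (B, L); returns probabilities and cache."""
        E_ = self.p["emb"][X]  # (B, L, E)
        pooled_parts, conv_cache = [], {}
        for k in self.config.kernel_sizes:
            h, zmax, pos, win = self._conv_pool(E_, X, k)
            pooled_parts.append(h)
            conv_cache[k] = (zmax, pos, win)
        pooled = np.concatenate(pooled_parts, axis=1)
        prob, cache = self._head(pooled, train, rng)
        cache["conv"] = conv_cache
        cache["X"] = X
        return prob, cache

    def score_tokens(self, notes_tokens: Sequence[Sequence[str]]) -> np.ndarray:
        """Eval-mode probabilities for token lists (length-bucketed batches)."""
        ids = [self.encode_tokens(t) for t in notes_tokens]
        order = np.argsort([len(a) for a in ids], kind="stable")
        out = np.zeros(len(ids))
        B = self.config.batch_size
        for s in range(0, len(order), B):
            chunk = order[s:s + B]
            L = max(len(ids[i]) for i in chunk)
            X = np.zeros((len(chunk), L), dtype=np.int64)
            for r, i in enumerate(chunk):
                X[r, :len(ids[i])] = ids[i]
            out[chunk], _ = self.forward(X, train=False)
        return out

    # -- backward -----------------------------------------------------------

    def _backward(self, cache: dict, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        g: dict[str, np.ndarray] = {}
        x_out = cache["x_out"]
        g["w_out"] = x_out.T @ dlogit
        g["b_out"] = np.array([dlogit.sum()])
        dx = dlogit[:, None] * self.p["w_out"][None, :]
        if "mask_out" in cache:
            dx = dx * cache["mask_out"]
        for i in (1, 0):
            dbn = dx * (cache[f"bn{i}"] > 0)
            xhat, inv = cache[f"xhat{i}"], cache[f"inv{i}"]
            g[f"gamma{i}"] = (dbn * xhat).sum(axis=0)
            g[f"beta{i}"] = dbn.sum(axis=0)
            B = dbn.shape[0]
            da = (self.p[f"gamma{i}"] * inv / B) * (
                B * dbn - dbn.sum(axis=0) - xhat * (dbn * xhat).sum(axis=0)
            )
            g[f"Wfc{i}"] = cache[f"x{i}"].T @ da
            g[f"bfc{i}"] = da.sum(axis=0)
            dx = da @ self.p[f"Wfc{i}"].T
            if f"mask{i}" in cache:
                dx = dx * cache[f"mask{i}"]
        # dx is now the gradient w.r.t. the pooled concatenation
        X = cache["X"]
        E = self.config.embed_dim
        F = self.config.filters_per_kernel
        demb = np.zeros_like(self.p["emb"])
        off = 0
        for k in self.config.kernel_sizes:
            zmax, pos, win = cache["conv"][k]
            gk = dx[:, off:off + F] * (zmax > 0)  # (B, F)
            off += F
            win_max = np.take_along_axis(
                win, pos[:, :, None], axis=1
            )  # gather (B, F, k*E): window that produced each max
            g[f"W{k}"] = np.einsum("bf,bfe->ef", gk, win_max)
            g[f"b{k}"] = gk.sum(axis=0)
            dwin = gk[:, :, None] * self.p[f"W{k}"].T[None, :, :]  # (B, F, k*E)
            tok_pos = pos[:, :, None] + np.arange(k)[None, None, :]  # (B, F, k)
            tok_ids = np.take_along_axis(
                X[:, :, None], tok_pos.reshape(X.shape[0], -1, 1), axis=1
            ).reshape(X.shape[0], F, k)
            np.add.at(demb, tok_ids.ravel(),
                      dwin.reshape(X.shape[0], F, k, E).reshape(-1, E))
        demb[0] = 0.0  # padding stays frozen
        g["emb"] = demb
        return g

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.config.lr, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name, grad in grads.items():
            if name not in self._adam:
                self._adam[name] = (np.zeros_like(grad), np.zeros_like(grad))
            m, v = self._adam[name]
            m[:] = b1 * m + (1 - b1) * grad
            v[:] = b2 * v + (1 - b2) * grad * grad
            mh = m / (1 - b1 ** t)
            vh = v / (1 - b2 ** t)
            self.p[name] -= lr * mh / (np.sqrt(vh) + eps)
        self.p["emb"][0] = 0.0

    # -- training -----------------------------------------------------------

    def fit(
        self,
        notes_tokens: Sequence[Sequence[str]],
        labels: Sequence[int],
        val_tokens: Sequence[Sequence[str]] | None = None,
        val_labels: Sequence[int] | None = None,
    ) -> "ConvNetClassifier":
        """Train for exactly config.epochs with Adam on binary cross-entropy.

        Minibatches are length-bucketed (sorted by note length, batch order
        shuffled each epoch) to bound padding waste; no early stopping.
        """
        y = np.asarray(labels, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        # start the output bias at the training prior log-odds so early
        # updates refine the ranking instead of relearning the base rate
        prior = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        if self._adam_t == 0:
            self.p["b_out"][0] = np.log(prior / (1 - prior))
        ids = [self.encode_tokens(t) for t in notes_tokens]
        order = np.argsort([len(a) for a in ids], kind="stable")
        Bsz = self.config.batch_size
        batches = [order[s:s + Bsz] for s in range(0, len(order), Bsz)]
        rng = self._train_rng
        for epoch in range(self.config.epochs):
            epoch_loss = 0.0
            for bi in rng.permutation(len(batches)):
                chunk = batches[bi]
                L = max(len(ids[i]) for i in chunk)
                X = np.zeros((len(chunk), L), dtype=np.int64)
                for r, i in enumerate(chunk):
                    X[r, :len(ids[i])] = ids[i]
                yb = y[chunk]
                prob, cache = self.forward(X, train=True, rng=rng)
                prob_c = np.clip(prob, 1e-9, 1 - 1e-9)
                loss = -(yb * np.log(prob_c) + (1 - yb) * np.log(1 - prob_c)).mean()
                epoch_loss += loss * len(chunk)
                dlogit = (prob - yb) / len(chunk)
                self._adam_step(self._backward(cache, dlogit))
            record = {"epoch": epoch, "train_loss": epoch_loss / len(ids)}
            if val_tokens is not None and val_labels is not None:
                vp = np.clip(self.score_tokens(val_tokens), 1e-9, 1 - 1e-9)
                vy = np.asarray(val_labels, dtype=float)
                record["val_loss"] = float(
                    -(vy * np.log(vp) + (1 - vy) * np.log(1 - vp)).mean()
                )
            self.history.append(record)
            logger.info("epoch %d: %s", epoch, record)
        return self


def train_convnet(
    train_tokens: Sequence[Sequence[str]],
    train_labels: Sequence[int],
    val_tokens: Sequence[Sequence[str]],
    val_labels: Sequence[int],
    config: ConvNetConfig,
    vocab_terms: Sequence[str],
    pretrained: EmbeddingMatrix | None = None,
) -> ConvNetClassifier:
    """Convenience wrapper: build and train a classifier."""
    clf = ConvNetClassifier(config, vocab_terms, pretrained)
    return clf.fit(train_tokens, train_labels, val_tokens, val_labels)


def save_checkpoint(clf: ConvNetClassifier, path) -> None:
    """Write parameters, batch-norm state and a config echo to an .npz file."""
    import json as _json
    from dataclasses import asdict

    arrays = {f"p_{k}": v for k, v in clf.p.items()}
    arrays.update({f"r_{k}": v for k, v in clf.running.items()})
    arrays["config_json"] = np.frombuffer(
        _json.dumps(asdict(clf.config)).encode(), dtype=np.uint8
    )
    arrays["terms"] = np.array(clf.terms)
    np.savez(path, **arrays)


def load_checkpoint(path) -> ConvNetClassifier:
    import json as _json

    with np.load(path, allow_pickle=False) as data:
        cfg_dict = _json.loads(bytes(data["config_json"]).decode())
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        cfg_dict["fc_sizes"] = tuple(cfg_dict["fc_sizes"])
        clf = ConvNetClassifier(ConvNetConfig(**cfg_dict),
                                [str(t) for t in data["terms"]])
        for k in list(clf.p):
            clf.p[k] = data[f"p_{k}"]
        for k in list(clf.running):
            clf.running[k] = data[f"r_{k}"]
    return clf


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributionRecord:
    """One n-gram's summed log-odds contribution for one note."""

    ngram: tuple[str, ...]
    contribution: float
    note_id: str = ""


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def attribute_ngrams(
    clf: ConvNetClassifier,
    note_tokens: Sequence[str],
    note_id: str = "",
) -> list[AttributionRecord]:
    """Rank the n-grams driving one note's score by log-odds occlusion.

    For each max-pool unit, the input window (an n-gram of that kernel's
    size) that produced the max activation is identified; the unit's
    contribution is logit(score) - logit(score with that unit's pooled
    activation zeroed). Contributions are summed per distinct n-gram and
    returned in descending order.
    """
    X = clf.encode_tokens(note_tokens)[None, :]
    prob, cache = clf.forward(X, train=False)
    pooled = cache["pooled"][0]
    base = _logit(float(prob[0]))
    id_to_term = {i + 1: t for i, t in enumerate(clf.terms)}
    contrib: dict[tuple[str, ...], float] = {}
    F = clf.config.filters_per_kernel
    off = 0
    for k in clf.config.kernel_sizes:
        _, pos, _ = cache["conv"][k]
        for f in range(F):
            j = off + f
            if pooled[j] == 0.0:
                continue
            occluded = pooled.copy()
            occluded[j] = 0.0
            p_occ, _ = clf._head(occluded[None, :], train=False)
            delta = base - _logit(float(p_occ[0]))
            p0 = int(pos[0, f])
            gram = tuple(
                id_to_term[i] for i in X[0, p0:p0 + k] if i != 0
            )
            if not gram:
                continue
            contrib[gram] = contrib.get(gram, 0.0) + delta
        off += F
    records = [
        AttributionRecord(ngram=g, contribution=c, note_id=note_id)
        for g, c in contrib.items()
    ]
    records.sort(key=lambda r: -r.contribution)
    return records


def attribution_table(records: Sequence[AttributionRecord]) -> str:
    """TSV: note_id, n-gram, contribution."""
    lines = ["note_id\tngram\tcontribution"]
    for r in records:
        lines.append(f"{r.note_id}\t{' '.join(r.ngram)}\t{r.contribution:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Benchmark adapter
# ---------------------------------------------------------------------------

class ConvNetModel:
    """Benchmark adapter around :class:`ConvNetClassifier`.

    If shared pretrained embeddings are supplied by the benchmark they are
    sliced to the fold vocabulary; otherwise skip-gram pretraining runs on the
    fold's training notes (``pretrain=True``) or embeddings start random.
    """

    name = "convnet"
    needs_embeddings = True

    def __init__(self, config: ConvNetConfig | None = None, pretrain: bool = True):
        self.config = config if config is not None else ConvNetConfig()
        self.pretrain = pretrain
        self.clf: ConvNetClassifier | None = None

    def fit(self, notes, labels, val_notes=None, val_labels=None, *,
            vocab: Vocabulary, seed: int = 0,
            embeddings: EmbeddingMatrix | None = None) -> "ConvNetModel":
        from dataclasses import replace
        cfg = replace(self.config, seed=seed)
        tokens = [n.tokens for n in notes]
        if embeddings is None and self.pretrain:
            embeddings = pretrain_embeddings(
                tokens, dim=cfg.embed_dim, seed=seed
            )
        self.clf = ConvNetClassifier(cfg, vocab.terms, embeddings)
        val_tokens = [n.tokens for n in val_notes] if val_notes is not None else None
        self.clf.fit(tokens, labels, val_tokens, val_labels)
        return self

    def score(self, notes: Sequence[ProcessedNote]) -> np.ndarray:
        if self.clf is None:
            raise RuntimeError("fit must be called before score")
        return self.clf.score_tokens([n.tokens for n in notes])
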