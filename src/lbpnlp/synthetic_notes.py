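"""Seeded generator of synthetic clinical-note corpora with planted signal.

Emulates a primary-care note corpus for acute-low-back-pain phenotyping:
roughly 5% of notes are positives that express acuity either through direct
keyword phrases or through paraphrases (plus medication/recommendation
support phrases); a fraction of controls contain *negated* keyword mentions;
per-token misspellings are injected; and ICD-10 M54.5 silver labels are
assigned with configurable discordance against the ground-truth labels
(defaults: precision 0.32, recall 0.68 of the code against truth). ICD-coded
controls carry chronic-low-back-pain text, mimicking the real failure mode of
the acuity-blind billing code.

Background text is template-sampled clinical filler; the phrase bank ships as
an editable JSON file. Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd

from .corpus import ClinicalNote, Corpus

logger = logging.getLogger(__name__)

_LETTERS = string.ascii_lowercase


@dataclass(frozen=True)
class PhraseBank:
    """Phrase inventory driving the generator (see data/phrasebank.json)."""

    direct_phrases: tuple[str, ...]
    direct_sentence_templates: tuple[str, ...]
    paraphrase_sentences: tuple[str, ...]
    support_sentences: tuple[str, ...]
    chronic_sentences: tuple[str, ...]
    negation_templates: tuple[str, ...]
    background_sentences: tuple[str, ...]
    other_icd_codes: tuple[str, ...]

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PhraseBank":
        if path is None:
            text = resources.files("lbpnlp.data").joinpath("phrasebank.json").read_text()
        else:
            text = Path(path).read_text(encoding="utf-8")
        raw = json.loads(text)
        return cls(**{k: tuple(v) for k, v in raw.items()})

    def signal_phrases(self) -> set[str]:
        """Space-joined n-grams a classifier could legitimately key on."""
        out: set[str] = set(self.direct_phrases)
        for s in self.paraphrase_sentences + self.support_sentences:
            out.add(s)
        return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic corpus.

    ``icd_precision``/``icd_recall`` parameterize the discordance of the
    M54.5 silver label against ground truth. Note lengths are lognormal in
    words, clipped to [min_words, max_words]; the upper clip defaults to 2000
    to keep experiments tractable (configurable up to real-corpus maxima).
    """

    n_notes: int = 2000
    positive_rate: float = 0.05
    paraphrase_rate: float = 0.4
    negation_rate: float = 0.1
    misspelling_rate: float = 0.01
    icd_precision: float = 0.32
    icd_recall: float = 0.68
    distractor_rate: float = 0.05
    length_log_mean: float = 4.8
    length_log_sd: float = 0.9
    min_words: int = 7
    max_words: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("positive_rate", "paraphrase_rate", "negation_rate",
                     "misspelling_rate", "icd_precision", "icd_recall",
                     "distractor_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_notes < 10:
            raise ValueError("n_notes must be >= 10")
        if self.min_words < 1 or self.max_words < self.min_words:
            raise ValueError("invalid length bounds")

    @property
    def control_code_rate(self) -> float:
        """Per-control probability of a false-positive M54.5 code.

        Solved from (icd_precision, icd_recall, positive_rate) so that in
        expectation P(truth | coded) = icd_precision and
        P(coded | truth) = icd_recall. Raises when infeasible.
        """
        if self.icd_precision == 0:
            raise ValueError("icd_precision must be > 0")
        p, r, q = self.positive_rate, self.icd_recall, self.icd_precision
        if p >= 1.0:
            return 0.0
        rate = r * p * (1 - q) / q / (1 - p)
        if rate > 1.0:
            feasible = r * p / (r * p + (1 - p))
            raise ValueError(
                f"infeasible icd_precision={q}: required false-positive codes "
                f"exceed available controls; minimum feasible precision at "
                f"these rates is {feasible:.4f}"
            )
        return rate


def _misspell(token: str, rng: np.random.Generator) -> str:
    """One random single-character edit (substitute / insert / delete)."""
    op = rng.integers(3)
    pos = int(rng.integers(len(token)))
    letter = _LETTERS[int(rng.integers(26))]
    if op == 0:
        return token[:pos] + letter + token[pos + 1:]
    if op == 1:
        return token[:pos] + letter + token[pos:]
    if len(token) > 1:
        return token[:pos] + token[pos + 1:]
    return token


def _apply_misspellings(
    sentence: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return sentence
    toks = sentence.split()
    out = []
    for t in toks:
        if len(t) >= 4 and rng.random() < rate:
            out.append(_misspell(t, rng))
        else:
            out.append(t)
    return " ".join(out)


def generate_note_text(
    is_positive: bool,
    coded_control: bool,
    config: SyntheticConfig,
    bank: PhraseBank,
    rng: np.random.Generator,
) -> str:
    """Assemble one note's raw text (background + planted signal sentences)."""
    # headroom keeps the note under max_words after signal/noise insertions
    upper = max(config.min_words, config.max_words - 60)
    target = int(np.clip(
        rng.lognormal(config.length_log_mean, config.length_log_sd),
        config.min_words, upper,
    ))
    sentences: list[str] = []
    words = 0
    while words < target:
        s = bank.background_sentences[int(rng.integers(len(bank.background_sentences)))]
        sentences.append(s)
        words += len(s.split())
    inserts: list[str] = []
    if is_positive:
        n_signal = int(rng.integers(1, 4))  # 1..3 insertions
        use_paraphrase = rng.random() < config.paraphrase_rate
        for _ in range(n_signal):
            if use_paraphrase:
                pool = bank.paraphrase_sentences + bank.support_sentences
                inserts.append(pool[int(rng.integers(len(pool)))])
            else:
                phrase = bank.direct_phrases[int(rng.integers(len(bank.direct_phrases)))]
                tmpl = bank.direct_sentence_templates[
                    int(rng.integers(len(bank.direct_sentence_templates)))
                ]
                inserts.append(tmpl.format(phrase=phrase))
                if rng.random() < 0.7:
                    inserts.append(
                        bank.support_sentences[int(rng.integers(len(bank.support_sentences)))]
                    )
    else:
        if rng.random() < config.negation_rate:
            phrase = bank.direct_phrases[int(rng.integers(len(bank.direct_phrases)))]
            tmpl = bank.negation_templates[int(rng.integers(len(bank.negation_templates)))]
            inserts.append(tmpl.format(phrase=phrase))
        if rng.random() < config.distractor_rate:
            inserts.append(
                bank.support_sentences[int(rng.integers(len(bank.support_sentences)))]
            )
        if coded_control:
            inserts.append(
                bank.chronic_sentences[int(rng.integers(len(bank.chronic_sentences)))]
            )
    for s in inserts:
        pos = int(rng.integers(len(sentences) + 1))
        sentences.insert(pos, s)
    sentences = [
        _apply_misspellings(s, config.misspelling_rate, rng) for s in sentences
    ]
    # sprinkle raw-noise fragments exercised by the cleaning patterns
    if rng.random() < 0.15:
        day = int(rng.integers(1, 28))
        sentences.append(f"visit documented {int(rng.integers(1, 13))}/{day}/2017")
    if rng.random() < 0.05:
        sentences.append("portal access at www.clinic-portal-example.com")
    return ". ".join(sentences) + "."


def generate_corpus(
    config: SyntheticConfig,
    bank: PhraseBank | None = None,
) -> Corpus:
    """Generate a labeled synthetic corpus, reproducible from config.seed."""
    if bank is None:
        bank = PhraseBank.load()
    control_code_rate = config.control_code_rate  # validates feasibility
    rng = np.random.default_rng(config.seed)
    notes: list[ClinicalNote] = []
    for i in range(config.n_notes):
        is_positive = bool(rng.random() < config.positive_rate)
        if is_positive:
            coded = bool(rng.random() < config.icd_recall)
            coded_control = False
        else:
            coded_control = bool(rng.random() < control_code_rate)
            coded = coded_control
        text = generate_note_text(is_positive, coded_control, config, bank, rng)
        codes: set[str] = set()
        if coded:
            codes.add("M54.5")
        for code in bank.other_icd_codes:
            if rng.random() < 0.08:
                codes.add(code)
        month = 1 + i % 12
        day = 1 + (i * 7) % 28
        notes.append(ClinicalNote(
            note_id=f"n{i:05d}",
            encounter_id=f"e{i:05d}",
            raw_text=text,
            icd10_codes=frozenset(codes),
            manual_label="acute_lbp" if is_positive else "other",
            timestamp=f"2017-{month:02d}-{day:02d}T09:00:00",
        ))
    return Corpus(
        notes=notes,
        provenance=f"synthetic corpus (n={config.n_notes}, seed={config.seed})",
    )


def describe_corpus(corpus: Corpus) -> dict:
    """Summary statistics: size, prevalence, lengths, ICD/manual confusion.

    Fields that cannot be computed (no codes, no reviewed labels) are NA.
    """
    n = len(corpus)
    lengths = np.array([note.word_count for note in corpus])
    manual = np.array([
        1 if note.manual_label == "acute_lbp"
        else (0 if note.manual_label == "other" else -1)
        for note in corpus
    ])
    coded = np.array([1 if "M54.5" in note.icd10_codes else 0 for note in corpus])
    reviewed = manual >= 0
    out: dict = {
        "n_notes": n,
        "n_reviewed": int(reviewed.sum()),
        "prevalence": float(manual[reviewed].mean()) if reviewed.any() else np.nan,
        "length_min": int(lengths.min()) if n else np.nan,
        "length_median": float(np.median(lengths)) if n else np.nan,
        "length_max": int(lengths.max()) if n else np.nan,
        "n_icd_coded": int(coded.sum()),
    }
    if reviewed.any() and coded.any():
        m, c = manual[reviewed], coded[reviewed]
        tp = int(np.sum((m == 1) & (c == 1)))
        fp = int(np.sum((m == 0) & (c == 1)))
        fn = int(np.sum((m == 1) & (c == 0)))
        tn = int(np.sum((m == 0) & (c == 0)))
        out.update({
            "icd_tp": tp, "icd_fp": fp, "icd_fn": fn, "icd_tn": tn,
            "icd_precision": tp / (tp + fp) if tp + fp else np.nan,
            "icd_recall": tp / (tp + fn) if tp + fn else np.nan,
        })
    else:
        out.update({k: np.nan for k in
                    ("icd_tp", "icd_fp", "icd_fn", "icd_tn",
                     "icd_precision", "icd_recall")})
    return out


def describe_corpus_table(corpus: Corpus) -> pd.DataFrame:
    """The :func:`describe_corpus` summary as a one-row DataFrame."""
    return pd.DataFrame([describe_corpus(corpus)])
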