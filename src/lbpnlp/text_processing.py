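"""Note preprocessing: sentence splitting, cleaning, lemmatization, vocabulary.

The pipeline turns raw note text into lists of lowercase lemma tokens per
sentence, removing punctuation, numeric tokens, URLs, emails and dates. A
minimum-count vocabulary is fitted on a training corpus; tokens outside the
vocabulary are corrected to the nearest vocabulary term by Levenshtein edit
distance (capped), or discarded.

Cleaning patterns are module-level constants so they can be inspected and
overridden; edit distances are computed with edlib.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Cleaning configuration
# ---------------------------------------------------------------------------

#: Removed from the raw text before sentence splitting.
URL_PATTERN = re.compile(r"(?:https?://|www\.)\S+|\b\S+\.(?:com|org|net|edu|gov)\b", re.I)
EMAIL_PATTERN = re.compile(r"\b[\w.+-]+@[\w-]+\.[\w.-]+\b")
#: Common numeric date shapes (3/12/2017, 2017-03-12, 12.3.17).
DATE_PATTERN = re.compile(r"\b\d{1,4}[/.-]\d{1,2}[/.-]\d{1,4}\b")

#: Sentence boundaries are punctuation-driven and applied before punctuation
#: removal (periods, question/exclamation marks, semicolons, newlines).
SENTENCE_BOUNDARY = re.compile(r"[.!?;\n]+")

#: A token is kept only if purely alphabetic (with internal apostrophes
#: stripped); this removes punctuation runs, bare numbers and mixed
#: alphanumerics such as dose strings ("10mg").
TOKEN_PATTERN = re.compile(r"[a-z']+|[0-9][\w/]*")

DISCARD = None  # sentinel returned by correct_oov for unmatchable tokens

# Small rule-based English noun lemmatizer (plural stripping with exceptions).
_IRREGULAR_LEMMAS = {
    "feet": "foot", "teeth": "tooth", "men": "man", "women": "woman",
    "children": "child", "mice": "mouse", "criteria": "criterion",
    "diagnoses": "diagnosis", "vertebrae": "vertebra",
}
_PLURAL_KEEP = {"analysis", "diagnosis", "stenosis", "osis", "us", "ss", "is"}


def lemmatize_token(token: str) -> str:
    """Map a lowercase token to a base form (noun-plural stripping only)."""
    if token in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[token]
    if len(token) > 3 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith(("ches", "shes", "sses", "xes", "zes")):
        return token[:-2]
    if (
        len(token) > 3
        and token.endswith("s")
        and not token.endswith(("ss", "us", "is"))
    ):
        return token[:-1]
    return token


@dataclass(frozen=True)
class ProcessedNote:
    """Sentence-segmented, cleaned token sequences for one note."""

    note_id: str
    sentences: tuple[tuple[str, ...], ...]

    @property
    def tokens(self) -> list[str]:
        """Flattened token sequence in original order."""
        return [t for sent in self.sentences for t in sent]

    def __len__(self) -> int:
        return sum(len(s) for s in self.sentences)


def clean_and_tokenize(
    raw_text: str, note_id: str = "", lemmatize: bool = True
) -> ProcessedNote:
    """Clean, sentence-split, tokenize and (optionally) lemmatize raw text.

    URLs, emails and dates are excised before sentence splitting; sentences
    are split on terminal punctuation and newlines; tokens are lowercased and
    kept only if purely alphabetic (numbers, doses and punctuation drop out).
    A note may legitimately yield zero tokens.
    """
    if not raw_text:
        raise ValueError("raw_text must be non-empty")
    text = URL_PATTERN.sub(" ", raw_text)
    text = EMAIL_PATTERN.sub(" ", text)
    text = DATE_PATTERN.sub(" ", text)
    text = text.lower()
    sentences: list[tuple[str, ...]] = []
    for chunk in SENTENCE_BOUNDARY.split(text):
        toks: list[str] = []
        for m in TOKEN_PATTERN.finditer(chunk):
            tok = m.group(0).strip("'")
            if not tok or not tok.isalpha():
                continue
            toks.append(lemmatize_token(tok) if lemmatize else tok)
        if toks:
            sentences.append(tuple(toks))
    return ProcessedNote(note_id=note_id, sentences=tuple(sentences))


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """Terms with corpus frequency >= min_count, contiguously indexed.

    Indexing is deterministic: descending frequency, ties lexicographic.
    """

    term_to_index: dict[str, int]
    frequencies: dict[str, int]
    min_count: int = 5
    source: str = ""
    _by_length: dict[int, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_length:
            for term in self.term_to_index:
                self._by_length.setdefault(len(term), []).append(term)

    def __contains__(self, term: str) -> bool:
        return term in self.term_to_index

    def __len__(self) -> int:
        return len(self.term_to_index)

    @property
    def terms(self) -> list[str]:
        """Terms in index order."""
        out = [""] * len(self.term_to_index)
        for t, i in self.term_to_index.items():
            out[i] = t
        return out

    def candidates_within(self, length: int, max_distance: int) -> Iterable[str]:
        """Terms whose length differs from ``length`` by at most the cap."""
        if max_distance == UNCAPPED:
            yield from self.term_to_index
            return
        for L in range(max(1, length - max_distance), length + max_distance + 1):
            yield from self._by_length.get(L, ())


def build_vocabulary(
    processed: Sequence[ProcessedNote], min_count: int = 5, source: str = ""
) -> Vocabulary:
    """Fit the minimum-count vocabulary over processed notes."""
    if not processed:
        raise ValueError("cannot fit a vocabulary on an empty note list")
    counts: Counter[str] = Counter()
    for note in processed:
        for sent in note.sentences:
            counts.update(sent)
    terms = [t for t, c in counts.items() if c >= min_count]
    if not terms:
        raise ValueError(
            f"no term reaches min_count={min_count} "
            f"({len(counts)} distinct terms seen)"
        )
    terms.sort(key=lambda t: (-counts[t], t))
    return Vocabulary(
        term_to_index={t: i for i, t in enumerate(terms)},
        frequencies={t: counts[t] for t in terms},
        min_count=min_count,
        source=source,
    )


UNCAPPED = float("inf")


def levenshtein(a: str, b: str, limit: int | None = None) -> int:
    """Levenshtein distance between two strings (edlib; -1 never returned).

    With ``limit`` set, any distance above it is reported as ``limit + 1``.
    """
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    k = -1 if limit is None else limit
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    return d if d >= 0 else (limit + 1)


def correct_oov(
    token: str,
    vocab: Vocabulary,
    max_distance: float = 2,
) -> str | None:
    """Correct an out-of-vocabulary token to its nearest vocabulary term.

    In-vocabulary tokens return unchanged. Otherwise the vocabulary term with
    minimum Levenshtein distance is returned, ties broken by higher corpus
    frequency then lexicographic order; if the minimum distance exceeds
    ``max_distance`` the token is discarded (returns :data:`DISCARD`).
    ``max_distance=float("inf")`` reproduces the uncapped nearest-term rule.
    """
    if not token:
        raise ValueError("token must be non-empty")
    if token in vocab:
        return token
    uncapped = max_distance == UNCAPPED
    cap = None if uncapped else int(max_distance)
    best: str | None = None
    best_key: tuple[int, int, str] | None = None
    for term in vocab.candidates_within(len(token), max_distance):
        d = levenshtein(token, term, limit=cap)
        if cap is not None and d > cap:
            continue
        key = (d, -vocab.frequencies[term], term)
        if best_key is None or key < best_key:
            best_key, best = key, term
            if not uncapped:
                cap = d  # no later candidate can beat a larger distance
    if best_key is None:
        return DISCARD
    return best


def encode_note(
    processed: ProcessedNote,
    vocab: Vocabulary,
    max_distance: float = 2,
    cache: dict[str, str | None] | None = None,
) -> ProcessedNote:
    """Map every token through OOV correction; discarded tokens are dropped.

    ``cache`` (token -> correction) may be shared across notes encoded against
    the same vocabulary.
    """
    if cache is None:
        cache = {}
    sentences: list[tuple[str, ...]] = []
    for sent in processed.sentences:
        toks: list[str] = []
        for tok in sent:
            if tok in vocab:
                toks.append(tok)
                continue
            if tok not in cache:
                cache[tok] = correct_oov(tok, vocab, max_distance=max_distance)
            corrected = cache[tok]
            if corrected is not DISCARD:
                toks.append(corrected)
        if toks:
            sentences.append(tuple(toks))
    return ProcessedNote(note_id=processed.note_id, sentences=tuple(sentences))


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """Serialize as a two-column TSV (term, index)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#min_count\t{vocab.min_count}\n")
        for term in vocab.terms:
            fh.write(f"{term}\t{vocab.term_to_index[term]}\n")


def load_vocabulary(path: str | Path) -> Vocabulary:
    term_to_index: dict[str, int] = {}
    min_count = 5
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, value = line.split("\t")
            if key == "#min_count":
                min_count = int(value)
            else:
                term_to_index[key] = int(value)
    # frequencies are not serialized; fall back to rank order for tie-breaking
    n = len(term_to_index)
    freqs = {t: n - i for t, i in term_to_index.items()}
    return Vocabulary(term_to_index=term_to_index, frequencies=freqs,
                      min_count=min_count, source=str(path))
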