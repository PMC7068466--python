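"""WordSearch: keyword-phrase counting with NegEx-style negation filtering.

Scans processed notes for acute-LBP keyword phrases ("acute low back pain",
"acute lbp", "acute low bp", "acute back pain"), marks each mention affirmed
or negated with a trigger/scope-window negation rule (NegEx), and squashes the
affirmed-mention count into a [0,1] score via ``1 - exp(-count)``. Any strictly
monotone squashing yields the same ranking, hence the same ROC/PR areas; the
exponential map is this implementation's choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .text_processing import ProcessedNote, clean_and_tokenize

logger = logging.getLogger(__name__)

#: The four acuity keyword phrases searched in the text.
DEFAULT_KEYWORD_PHRASES: tuple[tuple[str, ...], ...] = (
    ("acute", "low", "back", "pain"),
    ("acute", "lbp"),
    ("acute", "low", "bp"),
    ("acute", "back", "pain"),
)

AFFIRMED = "affirmed"
NEGATED = "negated"


@dataclass(frozen=True)
class NegationTriggers:
    """Trigger lexicon and scope window for the negation rule.

    ``pre`` triggers negate a mention appearing within ``window`` tokens after
    the trigger, unless a scope ``terminator`` intervenes; ``post`` triggers
    negate a mention within ``window`` tokens before them.
    """

    pre: tuple[tuple[str, ...], ...]
    post: tuple[tuple[str, ...], ...]
    terminators: frozenset[str]
    window: int = 5


DEFAULT_TRIGGERS = NegationTriggers(
    pre=(
        ("no",), ("not",), ("without",), ("deny",), ("denies",), ("denied",),
        ("negative", "for",), ("no", "evidence", "of"), ("no", "sign", "of"),
        ("rule", "out"), ("ruled", "out"), ("free", "of"), ("never",),
        ("absence", "of"),
    ),
    post=(("unlikely",), ("ruled", "out"), ("rule", "out"), ("resolved",)),
    terminators=frozenset({"but", "however", "although", "though", "yet",
                           "except", "aside"}),
    window=5,
)


def load_keyword_phrases(path: str | Path | None = None) -> tuple[tuple[str, ...], ...]:
    """Load keyword phrases (one per line) and preprocess them like notes."""
    if path is None:
        text = resources.files("lbpnlp.data").joinpath("keywords.txt").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    phrases = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        note = clean_and_tokenize(line)
        phrases.append(tuple(note.tokens))
    return tuple(p for p in phrases if p)


def load_triggers(path: str | Path | None = None, window: int = 5) -> NegationTriggers:
    """Load a trigger lexicon file: lines ``PRE|POST|TERM <phrase>``.

    Trigger tokens pass through the same lemmatization as note text so that
    surface forms like "denies" match their processed representation.
    """
    if path is None:
        text = resources.files("lbpnlp.data").joinpath("negex_triggers.txt").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    pre: list[tuple[str, ...]] = []
    post: list[tuple[str, ...]] = []
    term: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, _, phrase = line.partition(" ")
        toks = tuple(clean_and_tokenize(phrase).tokens)
        if not toks:
            continue
        if kind == "PRE":
            pre.append(toks)
        elif kind == "POST":
            post.append(toks)
        elif kind == "TERM":
            term.add(toks[0])
        else:
            raise ValueError(f"unknown trigger kind {kind!r} in {line!r}")
    return NegationTriggers(pre=tuple(pre), post=tuple(post),
                            terminators=frozenset(term), window=window)


@dataclass(frozen=True)
class KeywordMention:
    """One keyword-phrase match inside a sentence."""

    sentence_index: int
    start_token: int
    phrase: tuple[str, ...]
    polarity: str = AFFIRMED


def find_keyword_mentions(
    note: ProcessedNote,
    phrases: Sequence[Sequence[str]] = DEFAULT_KEYWORD_PHRASES,
) -> list[KeywordMention]:
    """Find all keyword-phrase matches, longest-match-first without overlap.

    Phrases must be preprocessed with the same pipeline as the note. Polarity
    is initially affirmed; apply :func:`negex_polarity` to resolve it.
    """
    ordered = sorted((tuple(p) for p in phrases), key=len, reverse=True)
    mentions: list[KeywordMention] = []
    for si, sent in enumerate(note.sentences):
        taken = [False] * len(sent)
        for phrase in ordered:
            L = len(phrase)
            if L == 0 or L > len(sent):
                continue
            for start in range(len(sent) - L + 1):
                if any(taken[start:start + L]):
                    continue
                if tuple(sent[start:start + L]) == phrase:
                    for j in range(start, start + L):
                        taken[j] = True
                    mentions.append(
                        KeywordMention(sentence_index=si, start_token=start,
                                       phrase=phrase)
                    )
    mentions.sort(key=lambda m: (m.sentence_index, m.start_token))
    return mentions


def _match_at(sent: Sequence[str], pos: int, phrase: tuple[str, ...]) -> bool:
    return tuple(sent[pos:pos + len(phrase)]) == phrase


def negex_polarity(
    sentence: Sequence[str],
    mention: KeywordMention,
    triggers: NegationTriggers = DEFAULT_TRIGGERS,
) -> str:
    """Resolve a mention's polarity with the trigger/scope-window rule.

    Negated iff a pre-trigger ends within ``window`` tokens before the mention
    with no scope terminator between trigger and mention, or a post-trigger
    starts within ``window`` tokens after it.
    """
    start = mention.start_token
    end = start + len(mention.phrase)  # one past the mention
    if start < 0 or end > len(sentence):
        raise ValueError("mention lies outside the sentence")
    w = triggers.window
    for trig in triggers.pre:
        L = len(trig)
        for pos in range(max(0, start - w - L + 1), start - L + 1):
            if not _match_at(sentence, pos, trig):
                continue
            gap_tokens = sentence[pos + L:start]
            if not any(t in triggers.terminators for t in gap_tokens):
                return NEGATED
    for trig in triggers.post:
        for pos in range(end, min(len(sentence) - len(trig), end + w - 1) + 1):
            if _match_at(sentence, pos, trig):
                gap_tokens = sentence[end:pos]
                if not any(t in triggers.terminators for t in gap_tokens):
                    return NEGATED
    return AFFIRMED


def annotate_mentions(
    note: ProcessedNote,
    phrases: Sequence[Sequence[str]] = DEFAULT_KEYWORD_PHRASES,
    triggers: NegationTriggers = DEFAULT_TRIGGERS,
) -> list[KeywordMention]:
    """Find mentions and resolve each one's polarity."""
    out = []
    for m in find_keyword_mentions(note, phrases):
        pol = negex_polarity(note.sentences[m.sentence_index], m, triggers)
        out.append(KeywordMention(m.sentence_index, m.start_token, m.phrase, pol))
    return out


def wordsearch_score(
    note: ProcessedNote,
    phrases: Sequence[Sequence[str]] = DEFAULT_KEYWORD_PHRASES,
    triggers: NegationTriggers = DEFAULT_TRIGGERS,
) -> float:
    """Score = 1 - exp(-count of affirmed keyword mentions), in [0, 1]."""
    count = sum(
        1 for m in annotate_mentions(note, phrases, triggers)
        if m.polarity == AFFIRMED
    )
    return 1.0 - math.exp(-count)


class WordSearchModel:
    """Benchmark adapter: unsupervised keyword scorer with fit/score API."""

    name = "wordsearch"
    needs_embeddings = False

    def __init__(
        self,
        phrases: Sequence[Sequence[str]] = DEFAULT_KEYWORD_PHRASES,
        triggers: NegationTriggers = DEFAULT_TRIGGERS,
    ) -> None:
        self.phrases = tuple(tuple(p) for p in phrases)
        self.triggers = triggers

    def fit(self, notes, labels, val_notes=None, val_labels=None, *,
            vocab=None, seed=0, embeddings=None) -> "WordSearchModel":
        return self  # no trainable state

    def score(self, notes: Sequence[ProcessedNote]) -> np.ndarray:
        return np.array(
            [wordsearch_score(n, self.phrases, self.triggers) for n in notes]
        )
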