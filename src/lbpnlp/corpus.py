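"""Reading, validating, filtering and writing clinical-note corpora.

A corpus is an ordered list of :class:`ClinicalNote` records. Notes carry a
free-text body, optional encounter/billing metadata (ICD-10 code set) and an
optional manual chart-review label (``acute_lbp`` / ``other`` / ``unreviewed``).

On-disk formats: JSONL (one object per line with keys ``note_id``,
``encounter_id``, ``text``, ``icd10``, ``label``, ``timestamp``) or a CSV with
the same column names (``icd10`` semicolon-separated). Prediction files are
CSVs with columns ``note_id, score, label, model, fold``.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

MANUAL_LABELS = ("acute_lbp", "other", "unreviewed")


@dataclass(frozen=True)
class ClinicalNote:
    """One clinical document with optional encounter metadata and labels."""

    note_id: str
    raw_text: str
    encounter_id: str | None = None
    icd10_codes: frozenset[str] = field(default_factory=frozenset)
    manual_label: str = "unreviewed"
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if not self.note_id:
            raise ValueError("note_id must be non-empty")
        if not self.raw_text:
            raise ValueError(f"note {self.note_id!r}: raw_text must be non-empty")
        if self.manual_label not in MANUAL_LABELS:
            raise ValueError(
                f"note {self.note_id!r}: manual_label {self.manual_label!r} "
                f"not in {MANUAL_LABELS}"
            )
        if not isinstance(self.icd10_codes, frozenset):
            object.__setattr__(self, "icd10_codes", frozenset(self.icd10_codes))

    @property
    def word_count(self) -> int:
        return len(self.raw_text.split())


@dataclass
class Corpus:
    """Ordered, stably iterable collection of notes with unique ids."""

    notes: list[ClinicalNote]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, note in enumerate(self.notes):
            if note.note_id in seen:
                raise ValueError(f"duplicate note_id {note.note_id!r} at record {i}")
            seen.add(note.note_id)

    def __len__(self) -> int:
        return len(self.notes)

    def __iter__(self) -> Iterator[ClinicalNote]:
        return iter(self.notes)

    def __getitem__(self, i: int) -> ClinicalNote:
        return self.notes[i]

    @property
    def note_ids(self) -> list[str]:
        return [n.note_id for n in self.notes]

    def get(self, note_id: str) -> ClinicalNote:
        for n in self.notes:
            if n.note_id == note_id:
                return n
        raise KeyError(note_id)


def _note_from_record(rec: dict, index: int) -> ClinicalNote:
    note_id = rec.get("note_id")
    text = rec.get("text")
    if note_id in (None, ""):
        raise ValueError(f"record {index}: missing note_id")
    if text in (None, ""):
        raise ValueError(f"record {index} (note_id={note_id!r}): missing text")
    codes = rec.get("icd10") or []
    if isinstance(codes, str):
        codes = [c for c in re.split(r"[;,\s]+", codes) if c]
    label = rec.get("label") or "unreviewed"
    enc = rec.get("encounter_id") or None
    ts = rec.get("timestamp") or None
    if isinstance(ts, float) and pd.isna(ts):
        ts = None
    return ClinicalNote(
        note_id=str(note_id),
        raw_text=str(text),
        encounter_id=None if enc is None else str(enc),
        icd10_codes=frozenset(str(c) for c in codes),
        manual_label=str(label),
        timestamp=None if ts is None else str(ts),
    )


def load_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Load a corpus from a JSONL or CSV file.

    ``format`` may be ``"jsonl"`` or ``"csv"``; if omitted it is inferred from
    the file suffix. Missing optional fields default (empty code set,
    ``unreviewed`` label). Missing ``note_id``/``text`` or duplicate ids raise
    :class:`ValueError` naming the offending record.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")
    records: list[dict]
    if format == "jsonl":
        records = []
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                records.append(json.loads(line))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            records = list(csv.DictReader(fh))
    notes = [_note_from_record(rec, i) for i, rec in enumerate(records)]
    return Corpus(notes=notes, provenance=f"loaded from {path} ({format})")


def save_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = [
        {
            "note_id": n.note_id,
            "encounter_id": n.encounter_id or "",
            "text": n.raw_text,
            "icd10": ";".join(sorted(n.icd10_codes)),
            "label": n.manual_label,
            "timestamp": n.timestamp or "",
        }
        for n in corpus
    ]
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for note, row in zip(corpus, rows):
                obj = dict(row)
                obj["icd10"] = sorted(note.icd10_codes)
                fh.write(json.dumps(obj, sort_keys=True) + "\n")
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else [
                "note_id", "encounter_id", "text", "icd10", "label", "timestamp"])
            writer.writeheader()
            writer.writerows(rows)


def filter_corpus(
    corpus: Corpus,
    min_words: int = 3,
    exclude_patterns: Sequence[str] = (),
) -> Corpus:
    """Drop short and duplicate notes.

    Removes notes whose whitespace-tokenized text has fewer than ``min_words``
    tokens, then exact-duplicate texts (outer whitespace trimmed), keeping the
    first occurrence. ``exclude_patterns`` are optional regexes; a note matching
    any of them is dropped. Removal counts per rule are logged and recorded in
    the returned corpus provenance. Raises if nothing survives.
    """
    if min_words < 1:
        raise ValueError("min_words must be >= 1")
    compiled = [re.compile(p) for p in exclude_patterns]
    kept: list[ClinicalNote] = []
    seen_texts: set[str] = set()
    n_short = n_dup = n_excluded = 0
    for note in corpus:
        if len(note.raw_text.split()) < min_words:
            n_short += 1
            continue
        if any(rx.search(note.raw_text) for rx in compiled):
            n_excluded += 1
            continue
        key = note.raw_text.strip()
        if key in seen_texts:
            n_dup += 1
            continue
        seen_texts.add(key)
        kept.append(note)
    if not kept:
        raise ValueError(
            f"filter_corpus removed every note (short={n_short}, "
            f"duplicate={n_dup}, excluded={n_excluded})"
        )
    summary = (
        f"filtered: removed {n_short} short (<{min_words} words), "
        f"{n_dup} duplicate, {n_excluded} pattern-excluded"
    )
    logger.info(summary)
    return Corpus(notes=kept, provenance=f"{corpus.provenance}; {summary}")


_LABEL_PRIORITY = {"acute_lbp": 2, "other": 1, "unreviewed": 0}


def join_progress_notes(corpus: Corpus) -> Corpus:
    """Concatenate notes sharing an encounter into one note per encounter.

    Member notes are ordered by timestamp (missing timestamps sort last), ties
    broken by note_id. The joined note takes the encounter_id as its note_id;
    manual labels merge by priority (``acute_lbp`` > ``other`` > ``unreviewed``)
    and code sets union. Notes without an encounter_id pass through unchanged.
    """
    groups: dict[str, list[ClinicalNote]] = {}
    order: list[tuple[str, str]] = []  # (kind, key) preserving first appearance
    singles: dict[str, ClinicalNote] = {}
    for note in corpus:
        if note.encounter_id is None:
            singles[note.note_id] = note
            order.append(("single", note.note_id))
        else:
            if note.encounter_id not in groups:
                order.append(("group", note.encounter_id))
            groups.setdefault(note.encounter_id, []).append(note)
    out: list[ClinicalNote] = []
    for kind, key in order:
        if kind == "single":
            out.append(singles[key])
            continue
        members = sorted(
            groups[key],
            key=lambda n: (n.timestamp is None, n.timestamp or "", n.note_id),
        )
        if len(members) == 1:
            out.append(replace(members[0], note_id=key))
            continue
        label = max((m.manual_label for m in members), key=_LABEL_PRIORITY.get)
        codes = frozenset().union(*(m.icd10_codes for m in members))
        out.append(
            ClinicalNote(
                note_id=key,
                raw_text="\n".join(m.raw_text for m in members),
                encounter_id=key,
                icd10_codes=codes,
                manual_label=label,
                timestamp=members[0].timestamp,
            )
        )
    return Corpus(notes=out, provenance=f"{corpus.provenance}; joined by encounter")


def save_predictions(df: pd.DataFrame, path: str | Path) -> None:
    """Write a predictions table (note_id, score, label, model, fold) as CSV."""
    cols = ["note_id", "score", "label", "model", "fold"]
    df.loc[:, cols].to_csv(path, index=False)


def load_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
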