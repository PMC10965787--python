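"""Record handling: de-identification placeholders, token cleaning, relevance.

The unit of analysis is the *session record*: a free-text note a clinician
writes after a therapy session.  Before scoring, records pass through a
best-effort de-identification pass (pattern-based placeholders in the style
of Dutch clinical de-identification tools), tokenization with cleaning
(lowercase; stopwords, numbers, single characters and underscore tokens
removed), and an automated relevance filter that drops records with fewer
than five words or without any sentiment-bearing word.

.. warning::
   :func:`pseudonymize` is a regex/gazetteer heuristic intended to make test
   fixtures and examples shareable.  It is **not** a compliance-grade
   de-identification tool.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import Lexicon, load_wordlist

__all__ = [
    "SessionRecord",
    "pseudonymize",
    "tokenize_and_clean",
    "relevance_filter_auto",
    "prepare_records",
    "read_records",
    "write_records_jsonl",
    "default_stopwords",
]


@dataclass(frozen=True)
class SessionRecord:
    """One clinician note with its position in a patient's timeline."""

    record_id: str
    patient_id: str
    seq: int
    text: str
    tokens: tuple[str, ...] | None = None
    relevant_auto: bool | None = None

    def __post_init__(self) -> None:
        if self.seq < 0:
            raise ValueError(f"record {self.record_id}: seq must be non-negative")


# --- de-identification -----------------------------------------------------

_RE_EMAIL = re.compile(r"\S+@\S+\.\w+")
_RE_URL = re.compile(r"(?:https?://|www\.)\S+")
_RE_PHONE = re.compile(r"(?<!\w)(?:\+31|0031|0)[\s-]?\d(?:[\s-]?\d){7,9}(?!\w)")
_RE_POSTCODE = re.compile(r"(?<!\w)\d{4}\s?[A-Za-z]{2}(?!\w)")
_RE_DATE = re.compile(
    r"(?<!\w)(?:\d{1,2}[-/]\d{1,2}[-/]\d{2,4}"
    r"|\d{1,2}\s+(?:januari|februari|maart|april|mei|juni|juli|augustus"
    r"|september|oktober|november|december)(?:\s+\d{4})?)(?!\w)",
    re.IGNORECASE,
)
_RE_AGE = re.compile(r"(?<!\w)\d{1,3}\s*jaar(?:\s+oud)?(?!\w)", re.IGNORECASE)
_RE_CAPWORD = re.compile(r"(?<![\w(])[A-Z][a-zà-öø-ÿ]+(?!\w)")
_RE_SENT_START = re.compile(r"(?:^|[.!?]\s+|\n\s*)$")

_PLACEHOLDER = re.compile(r"\((?:NAME|DATE|LOCATION)-\d+\)|\(AGE\)")

DEFAULT_GAZETTEER = frozenset(
    {"amsterdam", "rotterdam", "utrecht", "enschede", "groningen", "eindhoven"}
)


def pseudonymize(
    text: str,
    *,
    gazetteer: frozenset[str] = DEFAULT_GAZETTEER,
) -> str:
    """Replace identifying expressions with numbered placeholders.

    E-mail addresses, URLs, phone numbers and postal codes are deleted.
    Dates become ``(DATE-k)``, age expressions ``(AGE)``, gazetteer hits
    ``(LOCATION-k)`` and name-like capitalized tokens ``(NAME-k)``; numbering
    is per record, first occurrence = 1, with repeated surface forms reusing
    their number.  Name detection is heuristic: a capitalized alphabetic
    token counts as name-like when it occurs away from a sentence start (or
    also occurs mid-sentence elsewhere in the record).  Already-substituted
    placeholders are never re-replaced, so the pass is idempotent.
    """
    if not text:
        return text
    for rx in (_RE_EMAIL, _RE_URL, _RE_PHONE, _RE_POSTCODE):
        text = rx.sub("", text)
    text = re.sub(r"[ \t]+", " ", text).strip()

    counters: dict[str, dict[str, int]] = {"DATE": {}, "LOCATION": {}, "NAME": {}}

    def number(kind: str, surface: str) -> int:
        table = counters[kind]
        key = surface.lower()
        if key not in table:
            table[key] = len(table) + 1
        return table[key]

    text = _RE_DATE.sub(lambda m: f"(DATE-{number('DATE', m.group(0))})", text)
    text = _RE_AGE.sub("(AGE)", text)

    # Names: find capitalized tokens, decide which are name-like, then replace.
    mid_sentence = set()
    for m in _RE_CAPWORD.finditer(text):
        if not _RE_SENT_START.search(text[: m.start()]):
            mid_sentence.add(m.group(0))

    def cap_repl(m: re.Match) -> str:
        word = m.group(0)
        if word.lower() in gazetteer:
            return f"(LOCATION-{number('LOCATION', word)})"
        at_start = _RE_SENT_START.search(text[: m.start()]) is not None
        if at_start and word not in mid_sentence:
            return word
        return f"(NAME-{number('NAME', word)})"

    return _RE_CAPWORD.sub(cap_repl, text)


# --- tokenization ----------------------------------------------------------

_RE_LETTER_RUN = re.compile(r"[^\W\d_]+", re.UNICODE)


def tokenize_and_clean(
    text: str,
    stopwords: frozenset[str] = frozenset(),
    keep: frozenset[str] = frozenset(),
) -> tuple[str, ...]:
    """Lowercased letter-run tokens with the standard removals applied.

    Splits on non-letter boundaries (de-identification placeholders are
    dropped beforehand as non-words), lowercases, and removes stopwords,
    pure-number tokens, single-character tokens and tokens containing
    underscores.  Words in *keep* — the configured negators and
    intensifiers — survive stopword removal unconditionally, because losing
    a negator silently flips downstream scores.
    """
    text = _PLACEHOLDER.sub(" ", text)
    out = []
    for tok in _RE_LETTER_RUN.findall(text):
        tok = tok.lower()
        if len(tok) <= 1 or "_" in tok or tok.isdigit():
            continue
        if tok in stopwords and tok not in keep:
            continue
        out.append(tok)
    return tuple(out)


def relevance_filter_auto(record: SessionRecord, lexicon: Lexicon) -> bool:
    """Automated relevance rule: >=5 cleaned tokens and >=1 sentiment word."""
    if record.tokens is None:
        raise ValueError(f"record {record.record_id}: tokens not populated")
    if len(record.tokens) < 5:
        return False
    return any(lexicon.polarity(t) is not None for t in record.tokens)


def prepare_records(
    records: Iterable[SessionRecord],
    lexicon: Lexicon,
    stopwords: frozenset[str] = frozenset(),
) -> list[SessionRecord]:
    """Tokenize, clean and relevance-flag every record."""
    out = []
    for rec in records:
        tokens = tokenize_and_clean(rec.text, stopwords, keep=lexicon.modifiers)
        rec = replace(rec, tokens=tokens)
        rec = replace(rec, relevant_auto=relevance_filter_auto(rec, lexicon))
        out.append(rec)
    return out


def default_stopwords(modifiers: frozenset[str] = frozenset()) -> frozenset[str]:
    """Bundled Dutch stopword list minus the configured modifier words."""
    path = Path(__file__).parent / "data" / "demo_stopwords.tsv"
    return load_wordlist(path) - modifiers


# --- I/O -------------------------------------------------------------------

_REQUIRED_COLS = ("record_id", "patient_id", "seq", "text")


def read_records(path: str | Path) -> list[SessionRecord]:
    """Read session records from CSV or JSONL (record_id, patient_id, seq, text)."""
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        rows = [json.loads(line) for line in path.read_text(encoding="utf-8").splitlines() if line.strip()]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, dtype={"record_id": str, "patient_id": str})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = [
        SessionRecord(
            record_id=str(row.record_id),
            patient_id=str(row.patient_id),
            seq=int(row.seq),
            text="" if pd.isna(row.text) else str(row.text),
        )
        for row in df.itertuples()
    ]
    _check_seq_order(records)
    return records


def _check_seq_order(records: Sequence[SessionRecord]) -> None:
    last: dict[str, int] = {}
    for rec in records:
        prev = last.get(rec.patient_id)
        if prev is not None and rec.seq <= prev:
            raise ValueError(
                f"record {rec.record_id}: seq {rec.seq} not strictly increasing "
                f"for patient {rec.patient_id}"
            )
        last[rec.patient_id] = rec.seq


def write_records_jsonl(records: Iterable[SessionRecord], path: str | Path) -> None:
    """Cache cleaned records as JSONL (tokens included when populated)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            row = {
                "record_id": rec.record_id,
                "patient_id": rec.patient_id,
                "seq": rec.seq,
                "text": rec.text,
            }
            if rec.tokens is not None:
                row["tokens"] = list(rec.tokens)
            if rec.relevant_auto is not None:
                row["relevant_auto"] = rec.relevant_auto
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")
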