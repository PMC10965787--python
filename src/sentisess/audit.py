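"""Qualitative match diagnostics.

Lexicon-based scoring is only as good as its lexicon: domain-specific
expressions (e.g. recovery vocabulary in eating-disorder care) may be
missing, and general-purpose polarities can be wrong in context ("sporten"
reads positive generically but often signals compensation behaviour in an
anorexia context).  This module reports which words drove a record's score,
which context-list expressions the lexicon missed, and where lexicon and
context-list polarities conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .lexicon import Lexicon, LexiconFormatError, _POLARITY_TOKENS
from .preprocess import SessionRecord
from .scorer import SentimentResult

__all__ = [
    "ContextWordList",
    "load_context_words",
    "match_report",
    "missing_context_words",
    "polarity_conflicts",
]


@dataclass(frozen=True)
class ContextWordList:
    """Context-specific sentiment expressions (1-3 lowercase tokens each)."""

    entries: Mapping[str, int] = field(default_factory=dict)
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for expr, pol in self.entries.items():
            toks = expr.split()
            if not 1 <= len(toks) <= 3 or expr != expr.lower():
                raise ValueError(f"context expression {expr!r} must be 1-3 lowercase tokens")
            if pol not in (1, -1):
                raise ValueError(f"context expression {expr!r}: polarity must be +1/-1")
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "labels", dict(self.labels))

    def head(self, expr: str) -> str:
        """Head (last) token of an expression; the unit lexicons operate on."""
        return expr.split()[-1]


def load_context_words(path: str | Path) -> ContextWordList:
    """Read a context word list TSV: expression, polarity, context label."""
    entries: dict[str, int] = {}
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise LexiconFormatError(f"{path}:{lineno}: expected >=2 tab-separated fields")
        expr = " ".join(fields[0].lower().split())
        pol_tok = fields[1].strip().lower()
        if pol_tok not in _POLARITY_TOKENS:
            raise LexiconFormatError(f"{path}:{lineno}: unparseable polarity {fields[1]!r}")
        entries[expr] = _POLARITY_TOKENS[pol_tok]
        if len(fields) > 2:
            labels[expr] = fields[2].strip()
    return ContextWordList(entries=entries, labels=labels)


_REPORT_COLS = [
    "position",
    "word",
    "base",
    "prev1_effect",
    "prev2_effect",
    "bigram_score",
    "trigram_score",
]


def match_report(result: SentimentResult) -> pd.DataFrame:
    """Per-match table (one row per sentiment-bearing token, by position).

    For a record the relevance filter excluded, the table is empty and
    carries an explanatory note in ``DataFrame.attrs['note']``.
    """
    if not result.relevant_auto:
        df = pd.DataFrame(columns=_REPORT_COLS)
        df.attrs["note"] = f"record {result.record_id} excluded by the relevance filter"
        return df
    return pd.DataFrame(
        {
            "position": m.position,
            "word": m.word,
            "base": m.base,
            "prev1_effect": m.prev1_effect.value,
            "prev2_effect": m.prev2_effect.value,
            "bigram_score": m.bigram_score,
            "trigram_score": m.trigram_score,
        }
        for m in sorted(result.matches, key=lambda m: m.position)
    )


def missing_context_words(
    records: Iterable[SessionRecord],
    lexicon: Lexicon,
    context: ContextWordList,
) -> list[tuple[str, int]]:
    """Context expressions present in the corpus but invisible to the lexicon.

    An expression counts when its tokens occur contiguously in a record's
    cleaned token stream and its head word has no lexicon polarity.  Sorted
    by frequency (descending), ties lexicographic.
    """
    candidates = {
        expr: tuple(expr.split())
        for expr in context.entries
        if lexicon.polarity(context.head(expr)) is None
    }
    counts = {expr: 0 for expr in candidates}
    for rec in records:
        toks = rec.tokens
        if toks is None:
            continue
        for expr, parts in candidates.items():
            L = len(parts)
            counts[expr] += sum(
                1 for i in range(len(toks) - L + 1) if tuple(toks[i : i + L]) == parts
            )
    found = [(e, c) for e, c in counts.items() if c > 0]
    return sorted(found, key=lambda t: (-t[1], t[0]))


def polarity_conflicts(
    results: Iterable[SentimentResult],
    context: ContextWordList,
) -> list[tuple[str, int, int, int]]:
    """Matched words whose lexicon polarity opposes the context-list polarity.

    Returns ``(word, lexicon polarity, context polarity, match count)``
    tuples, sorted by count (descending) then word.  Multi-token context
    expressions contribute through their head word, since lexicon matches
    are single-word.
    """
    context_pol = {context.head(expr): pol for expr, pol in context.entries.items()}
    tally: dict[tuple[str, int, int], int] = {}
    for res in results:
        for m in res.matches:
            ctx = context_pol.get(m.word)
            if ctx is not None and ctx * m.base < 0:
                key = (m.word, m.base, ctx)
                tally[key] = tally.get(key, 0) + 1
    rows = [(w, b, c, n) for (w, b, c), n in tally.items()]
    return sorted(rows, key=lambda t: (-t[3], t[0]))
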