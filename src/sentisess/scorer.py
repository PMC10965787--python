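"""Lexicon-based bigram/trigram sentiment scoring of session records.

Each sentiment-bearing token gets a base score of +1 or -1 from the merged
lexicon.  Its *bigram* score is the base score modified by the immediately
preceding token: inverted when that token is a negator, doubled when it is
an intensifier.  Its *trigram* score additionally applies the same rule to
the token two positions back, with the two factors composing
multiplicatively (so ``niet heel goed`` scores ``+1 * 2 * -1 = -2``).  The
per-record channel score is the mean of the per-match n-gram scores; the
overall record score averages the bigram and trigram channels and is
clamped to [-1, 1], the range the method reports.

Because the intensifier doubles a score, channel means can exceed +/-1 on
intensifier-heavy records; the clamp reconciles this with the reported
[-1, 1] interval and is the only non-linearity in the scorer.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import Lexicon
from .preprocess import SessionRecord

__all__ = [
    "Effect",
    "Strategy",
    "TokenMatch",
    "SentimentResult",
    "find_matches",
    "score_record",
    "score_corpus",
    "results_to_frame",
    "write_results_csv",
]


class Effect(str, Enum):
    """What a preceding token does to a sentiment word's score."""

    NONE = "none"
    INVERT = "invert"
    REINFORCE = "reinforce"

    @property
    def factor(self) -> int:
        return {"none": 1, "invert": -1, "reinforce": 2}[self.value]


class Strategy(str, Enum):
    """How the per-record overall score aggregates the n-gram channels."""

    NGRAM_MEAN = "ngram_mean"  # mean of bigram and trigram channel finals
    TOKEN_MEAN = "token_mean"  # mean trigram score over matches


@dataclass(frozen=True)
class TokenMatch:
    """One sentiment-bearing token with its modifier context."""

    position: int
    word: str
    base: int
    prev1_effect: Effect
    prev2_effect: Effect

    @property
    def bigram_score(self) -> int:
        return self.base * self.prev1_effect.factor

    @property
    def trigram_score(self) -> int:
        return self.base * self.prev1_effect.factor * self.prev2_effect.factor


@dataclass(frozen=True)
class SentimentResult:
    """Per-record scoring outcome; ``overall`` is unset for irrelevant records."""

    record_id: str
    patient_id: str
    seq: int
    matches: tuple[TokenMatch, ...]
    bigram_final: float | None
    trigram_final: float | None
    overall: float | None
    relevant_auto: bool


def _effect_of(token: str | None, lexicon: Lexicon) -> Effect:
    if token is None:
        return Effect.NONE
    if token in lexicon.negators:
        return Effect.INVERT
    if token in lexicon.intensifiers:
        return Effect.REINFORCE
    return Effect.NONE


def find_matches(tokens: Sequence[str], lexicon: Lexicon) -> list[TokenMatch]:
    """One :class:`TokenMatch` per token carrying a lexicon polarity.

    Modifier effects are read off the cleaned token stream: ``prev1`` is the
    immediately preceding token, ``prev2`` the token two back; a missing
    predecessor contributes no effect.  A token that is both a modifier and
    a lexicon entry (only possible with the overlap-allow flag) acts as a
    modifier for its successor and as a sentiment word for itself.
    """
    matches = []
    for i, tok in enumerate(tokens):
        base = lexicon.polarity(tok)
        if base is None:
            continue
        prev1 = tokens[i - 1] if i >= 1 else None
        prev2 = tokens[i - 2] if i >= 2 else None
        matches.append(
            TokenMatch(
                position=i,
                word=tok,
                base=base,
                prev1_effect=_effect_of(prev1, lexicon),
                prev2_effect=_effect_of(prev2, lexicon),
            )
        )
    return matches


def _clamp(x: float) -> float:
    return max(-1.0, min(1.0, x))


def score_record(
    record: SessionRecord,
    lexicon: Lexicon,
    strategy: Strategy = Strategy.NGRAM_MEAN,
) -> SentimentResult:
    """Score one cleaned record; irrelevant records get no overall score."""
    if record.tokens is None:
        raise ValueError(f"record {record.record_id}: tokens not populated")
    relevant = record.relevant_auto
    if relevant is None:
        from .preprocess import relevance_filter_auto

        relevant = relevance_filter_auto(record, lexicon)
    matches = tuple(find_matches(record.tokens, lexicon))
    if not relevant or not matches:
        return SentimentResult(
            record_id=record.record_id,
            patient_id=record.patient_id,
            seq=record.seq,
            matches=matches,
            bigram_final=None,
            trigram_final=None,
            overall=None,
            relevant_auto=False,
        )
    m = len(matches)
    bigram_final = sum(t.bigram_score for t in matches) / m
    trigram_final = sum(t.trigram_score for t in matches) / m
    if strategy is Strategy.NGRAM_MEAN:
        overall = _clamp((bigram_final + trigram_final) / 2.0)
    else:
        overall = _clamp(trigram_final)
    return SentimentResult(
        record_id=record.record_id,
        patient_id=record.patient_id,
        seq=record.seq,
        matches=matches,
        bigram_final=bigram_final,
        trigram_final=trigram_final,
        overall=overall,
        relevant_auto=True,
    )


def score_corpus(
    records: Iterable[SessionRecord],
    lexicon: Lexicon,
    strategy: Strategy = Strategy.NGRAM_MEAN,
) -> list[SentimentResult]:
    """Score every record independently; deterministic, order-preserving."""
    return [score_record(rec, lexicon, strategy) for rec in records]


def results_to_frame(results: Iterable[SentimentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": r.record_id,
            "patient_id": r.patient_id,
            "seq": r.seq,
            "bigram_final": r.bigram_final,
            "trigram_final": r.trigram_final,
            "overall": r.overall,
            "relevant_auto": r.relevant_auto,
        }
        for r in results
    )


def write_results_csv(results: Iterable[SentimentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)
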