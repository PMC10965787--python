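"""Score standardization, the data-driven neutral band, and human ratings.

Raw automated scores and human 1-7 ratings live on different scales, so both
are z-standardized (pooled over all relevant records) before comparison.
Because standardized automated scores are never exactly zero, the "neutral"
category is an interval bounded by the standardized score closest to zero
from below and the one closest to zero from above (the study instance of
this band was (-0.03, 0.11)).  Human ratings are categorized on the raw
1-7 scale: below 4 negative, 4 neutral, above 4 positive; a "mixed" flag
(equal positive and negative content) may accompany a neutral rating and is
kept as metadata, mapping to neutral in all agreement statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "ScoreSet",
    "NeutralBand",
    "RatingSet",
    "standardize",
    "neutral_band_from_scores",
    "categorize_auto",
    "categorize_human",
    "average_human",
    "load_ratings",
]

Category = Literal["negative", "neutral", "positive"]
CATEGORIES: tuple[Category, ...] = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class ScoreSet:
    """Raw scores keyed by record id, with their pooled z-standardization."""

    values: Mapping[str, float]
    mean: float
    sd: float
    standardized: Mapping[str, float]


@dataclass(frozen=True)
class NeutralBand:
    """Closed z-score interval mapped to the neutral category."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= 0.0 <= self.hi):
            raise ValueError(f"neutral band must straddle zero, got [{self.lo}, {self.hi}]")


def standardize(values: Mapping[str, float], *, population: bool = False) -> ScoreSet:
    """Z-standardize a record->score map (sample SD by default).

    Raises ``ValueError`` on degenerate input (fewer than two scores, or all
    scores identical).
    """
    keys = list(values)
    arr = np.asarray([values[k] for k in keys], dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ValueError("standardization needs >=2 finite scores")
    sd = float(arr.std(ddof=0 if population else 1))
    if sd == 0.0 or not math.isfinite(sd):
        raise ValueError("standardization undefined: all scores identical")
    mean = float(arr.mean())
    z = (arr - mean) / sd
    return ScoreSet(
        values=dict(zip(keys, arr.tolist())),
        mean=mean,
        sd=sd,
        standardized=dict(zip(keys, z.tolist())),
    )


def neutral_band_from_scores(standardized: Mapping[str, float]) -> NeutralBand:
    """Band bounded by the first negative and first positive z-score.

    ``lo`` is the largest strictly negative standardized score, ``hi`` the
    smallest strictly positive one; exact zeros fall inside the band.  When
    all scores share one sign no band exists and a ``ValueError`` suggests
    supplying a manual band.
    """
    vals = np.asarray(list(standardized.values()), dtype=float)
    neg = vals[vals < 0]
    pos = vals[vals > 0]
    if neg.size == 0 or pos.size == 0:
        raise ValueError(
            "cannot derive a neutral band from one-signed scores; supply a manual band"
        )
    return NeutralBand(lo=float(neg.max()), hi=float(pos.min()))


def categorize_auto(z: float, band: NeutralBand) -> Category:
    """Map a standardized automated score to negative/neutral/positive.

    Band boundaries are inclusive-neutral: "negative" means strictly below
    ``lo`` and "positive" strictly above ``hi``.
    """
    if z < band.lo:
        return "negative"
    if z > band.hi:
        return "positive"
    return "neutral"


def categorize_human(score: int) -> Category:
    """Raw 1-7 rating to category: <4 negative, =4 neutral, >4 positive."""
    if not 1 <= score <= 7:
        raise ValueError(f"human rating {score} outside 1-7")
    if score < 4:
        return "negative"
    if score > 4:
        return "positive"
    return "neutral"


@dataclass(frozen=True)
class RatingSet:
    """One human rater's record ratings.

    ``scores`` maps record id -> rating in 1..7; records the rater marked
    irrelevant are absent.  ``mixed`` flags neutral records containing an
    equal amount of positive and negative sentiment.
    """

    rater_id: str
    scores: Mapping[str, int]
    mixed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for rid, s in self.scores.items():
            if not 1 <= int(s) <= 7:
                raise ValueError(f"rating {s} for record {rid} outside 1-7")
        bad = [r for r in self.mixed if self.scores.get(r) != 4]
        if bad:
            raise ValueError(f"mixed flag on non-neutral records: {sorted(bad)}")
        object.__setattr__(self, "scores", {r: int(s) for r, s in self.scores.items()})
        object.__setattr__(self, "mixed", frozenset(self.mixed))

    def categories(self) -> dict[str, Category]:
        return {r: categorize_human(s) for r, s in self.scores.items()}


def average_human(r1: RatingSet, r2: RatingSet, *, population: bool = False) -> ScoreSet:
    """Standardized per-record mean of two raters' scores.

    Only records rated (non-irrelevant) by *both* raters enter; the rest are
    excluded, mirroring pairwise deletion in the agreement statistics.
    """
    joint = sorted(set(r1.scores) & set(r2.scores))
    if not joint:
        raise ValueError("no records rated by both raters")
    means = {rid: (r1.scores[rid] + r2.scores[rid]) / 2.0 for rid in joint}
    return standardize(means, population=population)


def load_ratings(path: str | Path) -> dict[str, RatingSet]:
    """Read ratings CSV (record_id, rater_id, score, mixed) into RatingSets.

    ``score`` is 1-7 or NA/blank/"irrelevant"; ``mixed`` is 0/1.
    """
    df = pd.read_csv(Path(path), dtype={"record_id": str, "rater_id": str})
    out: dict[str, RatingSet] = {}
    for rater_id, grp in df.groupby("rater_id", sort=True):
        scores: dict[str, int] = {}
        mixed: set[str] = set()
        for row in grp.itertuples():
            raw = row.score
            if pd.isna(raw) or str(raw).strip().lower() in {"", "na", "irrelevant"}:
                continue
            scores[str(row.record_id)] = int(float(raw))
            if "mixed" in df.columns and not pd.isna(row.mixed) and int(row.mixed):
                mixed.add(str(row.record_id))
        out[str(rater_id)] = RatingSet(rater_id=str(rater_id), scores=scores, mixed=mixed)
    return out
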