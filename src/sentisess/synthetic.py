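"""Synthetic session-record corpora and simulated rater pairs.

The study's patient notes are private, so every pipeline stage is validated
on synthetic data with known ground truth instead:

* :func:`generate_corpus` assembles short clinician-note-like token streams
  from a polarity lexicon plus a controlled filler vocabulary.  Each record
  targets a category (positive / negative / neutral / mixed / irrelevant)
  and the generator computes the exact overall score the default scorer
  should produce via its own per-insertion bookkeeping — an implementation
  of the scoring semantics independent of the scorer, so their agreement
  cross-validates both.

* :func:`simulate_raters` draws two raters' scores from a two-way model
  ``observed_r = latent + bias_r + noise_r`` with the noise variance chosen
  so the population ICC(A,1) equals ``true_icc`` (given the latent sample
  variance and zero biases), then discretizes to the 1-7 scale with fixed
  equal-width cuts.  This supports parameter-recovery and CI-coverage checks
  of the agreement estimators.

The default corpus emulates the study conditions: 8 patients averaging
about 57 records each, with roughly 32% of records irrelevant and the
relevant remainder split toward negative and positive over neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import RatingSet
from .lexicon import Lexicon
from .preprocess import SessionRecord, default_stopwords

__all__ = [
    "CorpusSpec",
    "RaterSpec",
    "RaterSimulation",
    "generate_corpus",
    "simulate_raters",
    "FILLER_WORDS",
]

CATEGORY_KEYS = ("positive", "negative", "neutral", "mixed", "irrelevant")

# Neutral connective vocabulary; must stay disjoint from the demo lexicon,
# its modifiers and the bundled stopword list so generated adjacency and
# cleaning effects are fully controlled.
FILLER_WORDS: tuple[str, ...] = (
    "vandaag", "gesprek", "week", "afspraak", "thuis", "werk", "school",
    "samen", "besproken", "sessie", "volgende", "keer", "tijdens", "verder",
    "situatie", "afgelopen", "periode", "contact", "plan", "huiswerk",
    "oefening", "onderwerp", "uitleg", "weekend", "ouders", "eten",
    "dagboek", "doelen", "evaluatie", "vervolg",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Generation parameters for a synthetic session-record corpus.

    Defaults emulate the study corpus: 8 patients, 40-75 records each
    (mean ~57.5), ~31.5% irrelevant records, and the relevant mass split
    negative 29% / positive 25% / neutral 14% of all records, with 70% of
    the neutral mass flagged mixed.
    """

    n_patients: int = 8
    records_per_patient: int | tuple[int, int] = (40, 75)
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "positive": 0.25,
            "negative": 0.29,
            "neutral": 0.042,
            "mixed": 0.098,
            "irrelevant": 0.32,
        }
    )
    p_negation: float = 0.15
    p_intensifier: float = 0.10
    p_context_word: float = 0.05
    context_words: tuple[str, ...] = ("herstellijn", "lichaamsbeleving", "eetbui")
    seed: int = 0

    def __post_init__(self) -> None:
        mix = dict(self.category_mix)
        unknown = set(mix) - set(CATEGORY_KEYS)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"category mix must sum to 1, got {total}")
        if any(v < 0 for v in mix.values()):
            raise ValueError("category mix proportions must be non-negative")
        for p in (self.p_negation, self.p_intensifier, self.p_context_word):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "category_mix", mix)


def _clamp(x: float) -> float:
    return max(-1.0, min(1.0, x))


def _draw_filler(rng: np.random.Generator, fillers: Sequence[str]) -> str:
    return fillers[int(rng.integers(len(fillers)))]


def generate_corpus(
    spec: CorpusSpec,
    lexicon: Lexicon,
    *,
    fillers: Sequence[str] = FILLER_WORDS,
) -> tuple[list[SessionRecord], pd.DataFrame]:
    """Generate records plus a ground-truth table, deterministically per seed.

    Each non-irrelevant record is a chain of *insertion units* — two fillers
    followed by an optional modifier and a sentiment word — so every
    sentiment word's one- and two-back context is known by construction.
    The returned ground truth holds, per record, the intended category, the
    number of sentiment insertions, and the exact expected overall score of
    the default scorer (mean of bigram and trigram channel means, clamped
    to [-1, 1]), computed from the generator's own bookkeeping.

    Ground-truth exactness assumes downstream cleaning removes none of the
    generated tokens, which holds for the bundled stopword list (the filler
    vocabulary is disjoint from it by construction).
    """
    positives = sorted(w for w, p in lexicon.entries.items() if p == 1)
    negatives = sorted(w for w, p in lexicon.entries.items() if p == -1)
    negators = sorted(lexicon.negators)
    intensifiers = sorted(lexicon.intensifiers)
    if not positives or not negatives:
        raise ValueError("lexicon needs at least one positive and one negative entry")
    mix = spec.category_mix
    if (mix.get("mixed", 0) or mix.get("neutral", 0)) and (not positives or not negatives):
        raise ValueError("balanced categories need entries of both polarities")
    if mix.get("negative", 0) and spec.p_negation > 0 and not negators:
        raise ValueError("p_negation > 0 requires negators in the lexicon")

    reserved = set(lexicon.entries) | lexicon.modifiers | default_stopwords()
    fillers = [f for f in fillers if f not in reserved and len(f) > 1]
    if len(fillers) < 5:
        raise ValueError("not enough usable filler words")
    if any(w in reserved for w in spec.context_words):
        raise ValueError("context words must be out-of-lexicon, non-modifier, non-stopword")

    rng = np.random.default_rng(spec.seed)
    cats = list(mix)
    probs = np.asarray([mix[c] for c in cats], dtype=float)
    probs = probs / probs.sum()

    records: list[SessionRecord] = []
    truth_rows: list[dict] = []
    rec_counter = 0

    for p_idx in range(1, spec.n_patients + 1):
        patient_id = f"P{p_idx}"
        if isinstance(spec.records_per_patient, int):
            n_rec = spec.records_per_patient
        else:
            lo, hi = spec.records_per_patient
            n_rec = int(rng.integers(lo, hi + 1))
        for seq in range(1, n_rec + 1):
            rec_counter += 1
            record_id = f"R{rec_counter:05d}"
            category = cats[int(rng.choice(len(cats), p=probs))]
            tokens, n_units, sum_b, sum_t = _build_tokens(
                rng, category, spec, positives, negatives, negators, intensifiers, fillers
            )
            if n_units > 0:
                expected = _clamp((sum_b / n_units + sum_t / n_units) / 2.0)
            else:
                expected = np.nan
            records.append(
                SessionRecord(
                    record_id=record_id,
                    patient_id=patient_id,
                    seq=seq,
                    text=" ".join(tokens),
                )
            )
            truth_rows.append(
                {
                    "record_id": record_id,
                    "patient_id": patient_id,
                    "seq": seq,
                    "category": category,
                    "n_matches": n_units,
                    "expected_overall": expected,
                    "expected_relevant": category != "irrelevant",
                }
            )
    return records, pd.DataFrame(truth_rows)


def _draw_style(rng: np.random.Generator, spec: CorpusSpec) -> str:
    u = rng.random()
    if u < spec.p_negation:
        return "negated"
    if u < spec.p_negation + spec.p_intensifier:
        return "intensified"
    return "plain"


def _unit(
    rng: np.random.Generator,
    sign: int,
    style: str,
    positives: Sequence[str],
    negatives: Sequence[str],
    negators: Sequence[str],
    intensifiers: Sequence[str],
    fillers: Sequence[str],
) -> tuple[list[str], int, int]:
    """One insertion unit with net contribution of the requested sign.

    Returns (tokens, bigram contribution, trigram contribution).  A negated
    unit pairs a negator with a word of the opposite polarity so the net
    contribution keeps the requested sign; an intensified unit doubles it.
    """
    lead = [_draw_filler(rng, fillers), _draw_filler(rng, fillers)]
    if style == "negated" and negators:
        word = str(rng.choice(negatives if sign > 0 else positives))
        mod = negators[int(rng.integers(len(negators)))]
        return lead + [mod, word], sign, sign  # -base inverted
    if style == "intensified" and intensifiers:
        word = str(rng.choice(positives if sign > 0 else negatives))
        mod = intensifiers[int(rng.integers(len(intensifiers)))]
        return lead + [mod, word], 2 * sign, 2 * sign
    word = str(rng.choice(positives if sign > 0 else negatives))
    return lead + [word], sign, sign


def _build_tokens(
    rng: np.random.Generator,
    category: str,
    spec: CorpusSpec,
    positives: Sequence[str],
    negatives: Sequence[str],
    negators: Sequence[str],
    intensifiers: Sequence[str],
    fillers: Sequence[str],
) -> tuple[list[str], int, int, int]:
    tokens: list[str] = []
    sum_b = sum_t = n_units = 0

    def add_unit(sign: int, style: str) -> None:
        nonlocal sum_b, sum_t, n_units
        toks, b, t = _unit(rng, sign, style, positives, negatives, negators, intensifiers, fillers)
        tokens.extend(toks)
        sum_b += b
        sum_t += t
        n_units += 1

    if category == "irrelevant":
        if rng.random() < 0.5:
            tokens = [_draw_filler(rng, fillers) for _ in range(3)]  # < 5 words
        else:
            tokens = [_draw_filler(rng, fillers) for _ in range(7)]  # no sentiment words
        return tokens, 0, 0, 0

    if category in ("positive", "negative"):
        sign = 1 if category == "positive" else -1
        for _ in range(int(rng.integers(1, 5))):
            add_unit(sign, _draw_style(rng, spec))
    else:  # neutral / mixed: balanced pairs sharing one style so they cancel
        for _ in range(int(rng.integers(1, 3))):
            style = _draw_style(rng, spec)
            add_unit(1, style)
            add_unit(-1, style)

    if rng.random() < spec.p_context_word and spec.context_words:
        ctx = spec.context_words[int(rng.integers(len(spec.context_words)))]
        tokens.extend([_draw_filler(rng, fillers), ctx])
    while len(tokens) < 6:
        tokens.append(_draw_filler(rng, fillers))
    return tokens, n_units, sum_b, sum_t


@dataclass(frozen=True)
class RaterSpec:
    """Two-rater simulation parameters.

    ``true_icc`` is the population ICC(A,1) of the continuous observed
    scores under the two-way model; the error variance is derived from it,
    the latent (row) variance and the rater-bias (column) component.
    ``latent_var`` is the known variance of the latent scores; leave None to
    plug in the sample variance of the latent series supplied (adequate for
    one-off simulations, but recovery studies should pass the generating
    variance so replicates are unconditional draws from the stated model).
    ``scale_cuts`` are the ascending bounds discretizing the continuous
    scale to ratings 1-7.
    """

    true_icc: float = 0.6
    rater_bias: tuple[float, float] = (0.0, 0.0)
    latent_var: float | None = None
    scale_cuts: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    p_irrelevant_disagree: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.true_icc < 1.0:
            raise ValueError("true_icc must lie in (0, 1)")
        if list(self.scale_cuts) != sorted(self.scale_cuts) or len(self.scale_cuts) != 6:
            raise ValueError("scale_cuts must be 6 ascending bounds")
        if not 0.0 <= self.p_irrelevant_disagree <= 1.0:
            raise ValueError("p_irrelevant_disagree must lie in [0, 1]")
        if self.latent_var is not None and self.latent_var <= 0.0:
            raise ValueError("latent_var must be positive")


@dataclass(frozen=True)
class RaterSimulation:
    """Simulated pair of raters over a shared latent score series."""

    record_ids: tuple[str, ...]
    continuous: np.ndarray  # n x 2, pre-discretization observed scores
    ratings: tuple[RatingSet, RatingSet]


def simulate_raters(latent: Mapping[str, float], spec: RaterSpec) -> RaterSimulation:
    """Draw two raters' scores around shared latent record scores.

    ``observed_r = latent + bias_r + noise_r``.  The error variance solves
    ``rho = var_L / (var_L + theta_C + var_E)`` for ``rho = true_icc``,
    where ``var_L`` is the latent (row) variance and ``theta_C`` the
    rater-bias (column) component ``(b_1 - b_2)^2 / 2``, so the population
    ICC(A,1) of the continuous scores equals ``true_icc``; biases too large
    for the requested ICC are rejected.  Continuous scores are then cut
    into 1-7 ratings; each rater independently marks a record irrelevant
    (dropping it from their RatingSet) with probability
    ``p_irrelevant_disagree``.
    """
    ids = tuple(latent)
    vals = np.asarray([latent[r] for r in ids], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("latent scores must be finite")
    n = vals.size
    rng = np.random.default_rng(spec.seed)
    if spec.latent_var is not None:
        var_l = float(spec.latent_var)
    else:
        var_l = float(vals.var(ddof=1)) if n > 1 else 1.0
    rho = spec.true_icc
    b1, b2 = spec.rater_bias
    theta_c = (b1 - b2) ** 2 / 2.0
    var_e = var_l * (1.0 - rho) / rho - theta_c
    if var_e <= 0.0:
        raise ValueError(
            f"rater biases {spec.rater_bias} are too large for true_icc={rho}"
        )
    noise_sd = float(np.sqrt(var_e))
    continuous = np.empty((n, 2))
    for r in range(2):
        continuous[:, r] = vals + spec.rater_bias[r] + rng.normal(0.0, noise_sd, size=n)

    cuts = np.asarray(spec.scale_cuts)
    discrete = 1 + np.digitize(continuous, cuts)  # values in 1..7

    ratings = []
    for r in range(2):
        keep = rng.random(n) >= spec.p_irrelevant_disagree
        scores = {ids[i]: int(discrete[i, r]) for i in range(n) if keep[i]}
        ratings.append(RatingSet(rater_id=f"sim{r + 1}", scores=scores))
    return RaterSimulation(record_ids=ids, continuous=continuous, ratings=tuple(ratings))
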