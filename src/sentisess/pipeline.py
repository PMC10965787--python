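"""End-to-end orchestration: score a corpus, compare raters, export series.

These functions wire the modules together the way the full analysis runs:
clean and score records, standardize pooled scores, derive the neutral band,
build contingency tables and agreement estimates for every rater pairing
(automated vs each human, human vs human), and export per-patient
time-series of standardized scores.  The thin command-line interface in
:mod:`sentisess.cli` calls straight into this module.
"""

from __future__ import annotations

from dataclasses import asdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .agreement import (
    AgreementEstimate,
    ContingencyTable,
    WeightScheme,
    build_table,
    icc_a1,
    per_patient_icc,
    weighted_kappa,
)
from .calibration import (
    Category,
    NeutralBand,
    RatingSet,
    average_human,
    categorize_auto,
    neutral_band_from_scores,
    standardize,
)
from .lexicon import Lexicon
from .preprocess import SessionRecord, prepare_records
from .scorer import SentimentResult, Strategy, score_corpus

__all__ = [
    "pct",
    "score_pipeline",
    "auto_categories",
    "agreement_report",
    "series_frames",
    "report_to_jsonable",
]


def pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in summaries."""
    if total == 0:
        return 0.0
    exact = Decimal(100) * Decimal(count) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), ROUND_HALF_UP))


def score_pipeline(
    records: Iterable[SessionRecord],
    lexicon: Lexicon,
    stopwords: frozenset[str] = frozenset(),
    strategy: Strategy = Strategy.NGRAM_MEAN,
) -> tuple[list[SentimentResult], dict]:
    """Clean, relevance-filter and score records; return results + summary."""
    prepared = prepare_records(records, lexicon, stopwords)
    results = score_corpus(prepared, lexicon, strategy)
    n_total = len(results)
    n_rel = sum(r.relevant_auto for r in results)
    summary = {
        "n_records": n_total,
        "n_relevant_auto": n_rel,
        "pct_relevant_auto": pct(n_rel, n_total),
    }
    return results, summary


def auto_categories(
    results: Iterable[SentimentResult],
    band: NeutralBand | None = None,
) -> tuple[dict[str, Category], NeutralBand, dict[str, float]]:
    """Standardize relevant overall scores and categorize against the band.

    When no band is given it is derived from the data (the standardized
    score nearest zero on each side).  Returns the category map, the band
    used, and the standardized score map.
    """
    raw = {r.record_id: r.overall for r in results if r.relevant_auto}
    z = standardize(raw).standardized
    if band is None:
        band = neutral_band_from_scores(z)
    cats = {rid: categorize_auto(v, band) for rid, v in z.items()}
    return cats, band, z


def _joint_matrix(a: Mapping[str, float], b: Mapping[str, float]) -> np.ndarray:
    joint = sorted(set(a) & set(b))
    return np.asarray([[a[r], b[r]] for r in joint], dtype=float)


def agreement_report(
    results: list[SentimentResult],
    ratings: Mapping[str, RatingSet],
    *,
    weights: WeightScheme = "linear",
    alpha: float = 0.05,
    band: NeutralBand | None = None,
) -> dict:
    """All pairwise agreement analyses for the automated and human raters.

    For each automated-vs-human pairing: weighted kappa on categories and
    ICC(A,1) on pooled-standardized continuous scores, plus per-patient
    ICCs.  For the first two human raters: kappa on categories and ICC on
    raw 1-7 scores.  Comparisons without enough joint records are skipped
    with a note.
    """
    cats_auto, band, z_auto = auto_categories(results, band)
    report: dict = {
        "band": {"lo": band.lo, "hi": band.hi},
        "n_relevant_auto": len(z_auto),
        "comparisons": {},
        "per_patient": {},
        "tables": {},
    }
    rater_ids = sorted(ratings)
    for rid in rater_ids:
        rs = ratings[rid]
        name = f"auto_vs_{rid}"
        cats_h = rs.categories()
        try:
            table = build_table(cats_auto, cats_h)
            kap = weighted_kappa(table, weights, alpha)
        except ValueError as exc:
            report["comparisons"][name] = {"skipped": str(exc)}
        else:
            z_h = standardize({r: float(s) for r, s in rs.scores.items()}).standardized
            icc = icc_a1(_joint_matrix(z_auto, z_h), alpha=alpha)
            report["tables"][name] = table
            report["comparisons"][name] = {"kappa": kap, "icc": icc}
        try:
            report["per_patient"][name] = per_patient_icc(results, rs, alpha=alpha)
        except ValueError as exc:
            report["per_patient"][name] = {"skipped": str(exc)}

    if len(rater_ids) >= 2:
        r1, r2 = (ratings[rater_ids[0]], ratings[rater_ids[1]])
        name = f"{rater_ids[0]}_vs_{rater_ids[1]}"
        try:
            table = build_table(r1.categories(), r2.categories())
            kap = weighted_kappa(table, weights, alpha)
            raw = _joint_matrix(
                {r: float(s) for r, s in r1.scores.items()},
                {r: float(s) for r, s in r2.scores.items()},
            )
            icc = icc_a1(raw, alpha=alpha)
        except ValueError as exc:
            report["comparisons"][name] = {"skipped": str(exc)}
        else:
            report["tables"][name] = table
            report["comparisons"][name] = {"kappa": kap, "icc": icc}
    return report


def series_frames(
    results: list[SentimentResult],
    r1: RatingSet,
    r2: RatingSet,
) -> dict[str, pd.DataFrame]:
    """Per-patient time-series of standardized automated and human scores.

    One frame per patient with columns (seq, record_id, auto_z,
    human_avg_z).  Records either analysis abstained from carry NaN, never
    an imputed zero — the automated analysis often scores records the
    humans call irrelevant, and that divergence is the point of the plot.
    """
    z_auto = standardize(
        {x.record_id: x.overall for x in results if x.relevant_auto}
    ).standardized
    human = average_human(r1, r2).standardized
    frames: dict[str, list] = {}
    for res in sorted(results, key=lambda r: (r.patient_id, r.seq)):
        frames.setdefault(res.patient_id, []).append(
            {
                "seq": res.seq,
                "record_id": res.record_id,
                "auto_z": z_auto.get(res.record_id, np.nan),
                "human_avg_z": human.get(res.record_id, np.nan),
            }
        )
    return {p: pd.DataFrame(rows) for p, rows in frames.items()}


def report_to_jsonable(report: dict) -> dict:
    """Convert an agreement report to plain JSON-serializable structures."""

    def conv(obj):
        if isinstance(obj, AgreementEstimate):
            return asdict(obj)
        if isinstance(obj, ContingencyTable):
            rows_pct, cols_pct = obj.margin_percentages()
            return {
                "categories": list(obj.categories),
                "counts": obj.counts.tolist(),
                "n": obj.n,
                "column_percentages": np.round(obj.column_percentages(), 1).tolist(),
                "row_total_percentages": np.round(rows_pct, 1).tolist(),
                "column_total_percentages": np.round(cols_pct, 1).tolist(),
            }
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        return obj

    return conv(report)
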