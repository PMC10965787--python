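"""Inter-rater reliability: weighted Cohen's kappa and ICC(A,1).

Two estimators quantify how well two raters (human or automated) agree:

* **Weighted Cohen's kappa** for the ordered categories negative < neutral <
  positive.  With cell proportions :math:`p_{ij}` and agreement weights
  :math:`w_{ij}` (1 on the diagonal), :math:`\\kappa_w = (P_o - P_e)/(1 -
  P_e)` where :math:`P_o = \\sum w_{ij} p_{ij}` and :math:`P_e` uses the
  marginal products.  Linear weights :math:`w_{ij} = 1 - |i-j|/(C-1)` are
  the default; unweighted and quadratic are available.  The confidence
  interval uses the Fleiss-Cohen-Everitt large-sample standard error.

* **ICC(A,1)**: intraclass correlation under a two-way model with absolute
  agreement, single measure.  From the two-way ANOVA mean squares (rows =
  subjects, columns = raters, k raters),

  .. math::
     \\widehat{ICC}(A,1) = \\frac{MS_R - MS_E}
         {MS_R + (k-1)MS_E + \\tfrac{k}{n}(MS_C - MS_E)}

  with :math:`F = MS_R/MS_E` on :math:`(n-1, (n-1)(k-1))` degrees of
  freedom and the McGraw-Wong F-based confidence interval.  Absolute
  agreement charges systematic rater offsets against the correlation, which
  is why a constant shift between raters lowers the estimate.

Missing ratings are handled by pairwise deletion: every comparison is
restricted to the records both raters scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .calibration import CATEGORIES, Category, RatingSet, standardize
from .scorer import SentimentResult

__all__ = [
    "ContingencyTable",
    "AgreementEstimate",
    "build_table",
    "weighted_kappa",
    "icc_a1",
    "per_patient_icc",
    "kappa_weights",
    "interpret_kappa",
    "interpret_icc",
]

WeightScheme = Literal["unweighted", "linear", "quadratic"]


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 cross-tabulation of two raters' categories (rows = rater A)."""

    counts: np.ndarray
    categories: tuple[Category, ...] = CATEGORIES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.categories),) * 2 or (counts < 0).any():
            raise ValueError("counts must be a square non-negative matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column_percentages(self) -> np.ndarray:
        """Inner cells as a percentage of their column total."""
        tot = self.column_totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / tot
        return np.where(tot > 0, pct, 0.0)

    def margin_percentages(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column totals as percentages of the grand total."""
        n = float(self.n)
        return 100.0 * self.row_totals() / n, 100.0 * self.column_totals() / n


@dataclass(frozen=True)
class AgreementEstimate:
    """Point estimate, CI and test statistics for one agreement comparison."""

    kind: str
    estimate: float
    ci_lo: float
    ci_hi: float
    alpha: float
    n_pairs: int
    interpretation: str
    se: float | None = None
    f_value: float | None = None
    df1: int | None = None
    df2: int | None = None
    p_value: float | None = None


def interpret_kappa(k: float) -> str:
    """Landis-Koch verbal bands for kappa."""
    if k < 0:
        return "none"
    if k <= 0.20:
        return "slight"
    if k <= 0.40:
        return "fair"
    if k <= 0.60:
        return "moderate"
    if k <= 0.80:
        return "substantial"
    return "almost perfect"


def interpret_icc(r: float) -> str:
    """Koo-Li verbal bands for the ICC."""
    if r < 0.50:
        return "poor"
    if r < 0.75:
        return "moderate"
    if r <= 0.90:
        return "good"
    return "excellent"


def build_table(
    cats_a: Mapping[str, Category],
    cats_b: Mapping[str, Category],
    categories: Sequence[Category] = CATEGORIES,
) -> ContingencyTable:
    """Cross-tabulate two category maps over their shared record ids."""
    joint = set(cats_a) & set(cats_b)
    if not joint:
        raise ValueError("no records categorized by both raters")
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for rid in joint:
        counts[index[cats_a[rid]], index[cats_b[rid]]] += 1
    return ContingencyTable(counts=counts, categories=tuple(categories))


def kappa_weights(n_categories: int, scheme: WeightScheme) -> np.ndarray:
    """Agreement weight matrix: 1 on the diagonal, decreasing with distance."""
    i, j = np.indices((n_categories, n_categories))
    d = np.abs(i - j) / (n_categories - 1)
    if scheme == "unweighted":
        return (d == 0).astype(float)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(
    table: ContingencyTable,
    weights: WeightScheme = "linear",
    alpha: float = 0.05,
) -> AgreementEstimate:
    """Weighted Cohen's kappa with a large-sample (Fleiss-Cohen-Everitt) CI."""
    n = table.n
    if n < 2:
        raise ValueError("kappa needs at least 2 paired observations")
    p = table.counts / n
    w = kappa_weights(len(table.categories), weights)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(pi, pj)).sum())
    if np.isclose(pe, 1.0):
        raise ValueError("degenerate marginals: expected agreement is 1")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance of weighted kappa.
    w_row = w @ pj          # E_j[w_ij] per row i
    w_col = pi @ w          # E_i[w_ij] per column j
    term = (w - np.add.outer(w_row, w_col) * (1.0 - kappa)) ** 2
    var = (float((p * term).sum()) - (kappa - pe * (1.0 - kappa)) ** 2) / (
        n * (1.0 - pe) ** 2
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    # one-sided test of kappa = 0 uses the SE under H0; for the CI the
    # estimated-SE interval matches reported symmetric intervals
    p_value = float(2.0 * stats.norm.sf(abs(kappa) / se)) if se > 0 else 0.0
    return AgreementEstimate(
        kind=f"kappa_{weights}",
        estimate=float(kappa),
        ci_lo=float(max(-1.0, kappa - z * se)),
        ci_hi=float(min(1.0, kappa + z * se)),
        alpha=alpha,
        n_pairs=n,
        interpretation=interpret_kappa(kappa),
        se=se,
        p_value=p_value,
    )


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way single-observation ANOVA mean squares (rows, columns, error)."""
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return float(msr), float(msc), float(mse)


def icc_a1(scores: np.ndarray, alpha: float = 0.05) -> AgreementEstimate:
    """ICC(A,1) for an n x k matrix of paired scores (k raters, usually 2).

    Rows with any missing value are dropped first (pairwise deletion).
    Raises ``ValueError`` with fewer than 3 complete rows or when all scores
    are identical.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("scores must be an n x k matrix with k >= 2")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 complete pairs")
    if np.allclose(x, x.flat[0]):
        raise ValueError("ICC undefined: all scores identical")
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    estimate = (msr - mse) / denom
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse > 0:
        f_value = msr / mse
        p_value = float(stats.f.sf(f_value, df1, df2))
    else:
        f_value = np.inf
        p_value = 0.0

    if mse == 0.0 and msc == 0.0:
        # exact agreement: estimate is 1 and the interval collapses
        ci_lo = ci_hi = 1.0
    else:
        r = estimate
        a = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
        b = 1.0 + (k * r * (n - 1)) / (n * (1.0 - r)) if r < 1.0 else np.inf
        num_v = (a * msc + b * mse) ** 2
        den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else 1.0
        f_lo = stats.f.ppf(1.0 - alpha / 2.0, df1, v)
        f_hi = stats.f.ppf(1.0 - alpha / 2.0, v, df1)
        ci_lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
    return AgreementEstimate(
        kind="icc_a1",
        estimate=float(estimate),
        ci_lo=float(ci_lo),
        ci_hi=float(min(ci_hi, 1.0)),
        alpha=alpha,
        n_pairs=n,
        interpretation=interpret_icc(estimate),
        f_value=float(f_value),
        df1=df1,
        df2=df2,
        p_value=p_value,
    )


def per_patient_icc(
    results: Iterable[SentimentResult],
    ratings: RatingSet,
    *,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> dict[str, AgreementEstimate]:
    """ICC(A,1) per patient between automated and one rater's scores.

    Both series are z-standardized on the pooled corpus first, then each
    patient's jointly available records form the paired matrix; patients
    with fewer than *min_pairs* joint records are skipped.
    """
    results = list(results)
    auto_raw = {r.record_id: r.overall for r in results if r.relevant_auto}
    if len(auto_raw) < 2 or len(ratings.scores) < 2:
        raise ValueError("not enough scored records to standardize")
    auto_z = standardize(auto_raw).standardized
    human_z = standardize({r: float(s) for r, s in ratings.scores.items()}).standardized
    patient_of = {r.record_id: r.patient_id for r in results}

    by_patient: dict[str, list[tuple[float, float]]] = {}
    for rid in sorted(set(auto_z) & set(human_z)):
        by_patient.setdefault(patient_of[rid], []).append((auto_z[rid], human_z[rid]))

    out: dict[str, AgreementEstimate] = {}
    for patient, pairs in sorted(by_patient.items()):
        if len(pairs) < min_pairs:
            continue
        try:
            out[patient] = icc_a1(np.asarray(pairs), alpha=alpha)
        except ValueError:
            continue
    return out
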