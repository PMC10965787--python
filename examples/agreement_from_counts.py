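"""Agreement statistics from a printed-style contingency table and pairs.

The 3x3 table cross-tabulates two raters over negative/neutral/positive.
Weighted kappa corrects observed agreement for chance given the marginals;
linear weights give partial credit for near-miss disagreements.  ICC(A,1)
instead treats the scores as continuous and charges systematic offsets
between raters against the agreement.
"""

import numpy as np

from sentisess.agreement import ContingencyTable, icc_a1, weighted_kappa

counts = np.array([[106, 14, 5], [14, 43, 4], [7, 13, 57]])
table = ContingencyTable(counts)
print(f"n = {table.n}, row totals {table.row_totals()}, "
      f"column totals {table.column_totals()}")
for scheme in ("unweighted", "linear", "quadratic"):
    est = weighted_kappa(table, scheme)
    print(f"kappa ({scheme:10s}) = {est.estimate:.3f} "
          f"[{est.ci_lo:.3f}, {est.ci_hi:.3f}] -> {est.interpretation}")

# a rater pair with a constant offset: high consistency, penalized agreement
x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
est = icc_a1(x)
print(f"\nICC(A,1) of an offset pair = {est.estimate:.3f} "
      f"(F({est.df1},{est.df2}) = {est.f_value}, {est.interpretation})")
print("the offset keeps it below 1 even though the rankings agree perfectly")
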