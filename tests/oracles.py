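"""Brute-force reference implementations used only as test oracles.

Each oracle recomputes a quantity by the most explicit route available —
materializing every n-gram window, summing every square in the ANOVA by
loops, tallying the kappa weight table cell by cell — independently of the
library's vectorized or incremental code paths.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_score_record(tokens, lexicon, strategy="ngram_mean"):
    """Window-enumeration scorer: explicit (prev2, prev1, word) tables.

    Returns (bigram_final, trigram_final, overall) or None when the record
    has no sentiment-bearing tokens.
    """

    def factor(tok):
        if tok is None:
            return 1
        if tok in lexicon.negators:
            return -1
        if tok in lexicon.intensifiers:
            return 2
        return 1

    bigrams = []
    trigrams = []
    for i, tok in enumerate(tokens):
        base = lexicon.entries.get(tok)
        if base is None:
            continue
        window = (
            tokens[i - 2] if i >= 2 else None,
            tokens[i - 1] if i >= 1 else None,
            tok,
        )
        bigrams.append(base * factor(window[1]))
        trigrams.append(base * factor(window[1]) * factor(window[0]))
    if not bigrams:
        return None
    bf = sum(bigrams) / len(bigrams)
    tf = sum(trigrams) / len(trigrams)
    if strategy == "ngram_mean":
        overall = (bf + tf) / 2.0
    else:
        overall = tf
    return bf, tf, max(-1.0, min(1.0, overall))


def oracle_weighted_kappa(counts, scheme):
    """Cell-by-cell Po/Pe tally of weighted kappa."""
    counts = np.asarray(counts, dtype=float)
    c = counts.shape[0]
    n = counts.sum()
    po = pe = 0.0
    for i in range(c):
        for j in range(c):
            d = abs(i - j) / (c - 1)
            if scheme == "unweighted":
                w = 1.0 if i == j else 0.0
            elif scheme == "linear":
                w = 1.0 - d
            else:
                w = 1.0 - d * d
            po += w * counts[i, j] / n
            pe += w * (counts[i, :].sum() / n) * (counts[:, j].sum() / n)
    return (po - pe) / (1.0 - pe)


def oracle_icc_a1(x):
    """ICC(A,1) by explicit loop-based sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
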