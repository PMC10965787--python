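# sentisess

Lexicon-based sentiment analysis of clinician-written therapy session
records, with the inter-rater validation machinery needed to judge whether
such an automated analysis can stand in for human raters.

Mental-health clinicians write a free-text note after every therapy
session.  Tracking the sentiment of those notes over time is a cheap,
passive signal of treatment progress — if an automated reading of the notes
agrees well enough with how trained human raters read them.  `sentisess`
implements both sides of that comparison for Dutch clinical text and is
aimed at clinical-NLP researchers who want to run or stress-test this kind
of validation study without access to (private) patient data.

## Method

**Scoring.**  Each record is cleaned (lowercased; stopwords, numbers,
single-character and underscore tokens removed) and scanned against a
merged polarity lexicon (primary + domain lexicon + adjustment dictionary).
A sentiment-bearing token *w* with polarity *s(w) ∈ {+1, −1}* is scored
through the two tokens preceding it:

- bigram score: `s(w) · f(prev1)`
- trigram score: `s(w) · f(prev1) · f(prev2)`

with `f = −1` for a negator ("niet goed"), `f = 2` for an intensifier
("heel goed"), `f = 1` otherwise.  Channel finals are the per-record means
of those scores, and the overall record score is the mean of the two
channels, clamped to `[−1, 1]`.  Records with fewer than five cleaned
tokens or no sentiment word are excluded as irrelevant.

**Calibration.**  Overall scores are z-standardized pooled over the
relevant corpus.  "Neutral" is the closed band between the standardized
score nearest zero from below and from above (e.g. `(−0.03, 0.11)`);
scores beyond the band are negative/positive.  Human 1–7 ratings are
categorized as `<4` negative, `=4` neutral, `>4` positive.

**Agreement.**  Categorical agreement uses weighted Cohen's kappa,
`κ_w = (P_o − P_e)/(1 − P_e)` with linear distance weights by default and a
Fleiss–Cohen–Everitt large-sample confidence interval.  Continuous
agreement uses ICC(A,1) — two-way model, absolute agreement, single
measure — from the ANOVA mean squares
`(MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)` with the
McGraw–Wong F-based confidence interval, overall and per patient.

**Synthetic data.**  A corpus generator assembles records with known
category and an exactly known expected score (its bookkeeping is an
independent implementation of the scoring semantics), and a rater
simulator draws two raters from a two-way model with a chosen true ICC —
so estimator recovery, CI coverage and every pipeline stage are testable
end to end.

## Worked example

```bash
python examples/score_a_note.py
```

```
n1: 'Patiënt voelt zich vandaag niet goed en erg somber.'
  tokens: ['patiënt', 'voelt', 'zich', 'vandaag', 'niet', 'goed', 'erg', 'somber']
 position   word  base prev1_effect prev2_effect  bigram_score  trigram_score
        5   goed     1       invert         none            -1             -1
        7 somber    -1         none         none            -1             -1
  bigram mean -1.00, trigram mean -1.00 -> overall -1.00
```

"goed" (+1) is inverted by the preceding negator "niet"; "somber" (−1) is
unmodified; both n-gram channels average to −1, so the record reads as
clearly negative.  In the second note of the same example, "heel trots"
doubles to +2 and the channel means (+1.5 and +2.0) clamp to an overall of
+1.00.

The other examples cover the full synthetic study (`synthetic_study.py`:
corpus → scores → simulated raters → kappa/ICC report, printing e.g.
`sim1_vs_sim2: kappa=0.72 ... ICC(A,1)=0.76` for raters simulated at a
true ICC of 0.8), agreement statistics from printed-style tables
(`agreement_from_counts.py`), and lexicon gap auditing
(`audit_lexicon_gaps.py`).

A thin CLI wraps the same pipeline for file-based runs:

```bash
sentisess simulate --config cfg.yaml --out out/   # corpus + ratings + truth
sentisess score    --config cfg.yaml --out out/   # per-record scores
sentisess agree    --config cfg.yaml --out out/   # kappa/ICC report
sentisess series   --config cfg.yaml --out out/   # per-patient time series
sentisess audit    --config cfg.yaml --out out/   # lexicon gap report
```

A small Dutch demo lexicon (~40 words plus negator/intensifier lists) ships
for examples and tests; real analyses require user-supplied lexicons.

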