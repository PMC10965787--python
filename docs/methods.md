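# Methods

This note documents the models and procedures `sentisess` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Scoring model

The scorer is a top-down lexicon method with n-gram valence shifters.  A
merged lexicon maps words to a binary polarity (+1/−1); two modifier sets
hold negators and intensifiers.  For a sentiment-bearing token at position
*i* in the cleaned stream:

- `bigram(i) = base · f(token[i−1])`
- `trigram(i) = base · f(token[i−1]) · f(token[i−2])`

with `f(negator) = −1`, `f(intensifier) = 2`, `f(anything else) = 1`, and a
missing predecessor contributing factor 1.  Channel finals are the means of
these scores over all matches; the overall record score is the mean of the
two channel finals, clamped to [−1, 1].

Open points resolved here, and why:

- **Channel combination.**  The per-channel formulas (sum of n-gram scores
  over the number of n-grams) are explicit, but how the two channels merge
  into one overall score is not.  Default: the mean of the two channel
  finals (`ngram_mean`), which preserves both channel formulas verbatim; a
  `token_mean` alternative (mean trigram score per match) is available.
- **Clamping.**  The ×2 intensifier lets channel finals reach ±2, which
  conflicts with the stated [−1, 1] range of the overall score; the overall
  is therefore clamped.  Clamping is the scorer's only non-linearity; sign
  symmetry survives it because the clamp is odd.
- **Modifier composition.**  With two modifiers in a trigram the factors
  compose multiplicatively regardless of order: double negation cancels,
  negator+intensifier gives −2.  This is the minimal consistent extension
  of the bigram rules.
- **Record-initial matches** score with factor 1 and count in the
  denominator.
- A token that is both modifier and lexicon entry is rejected by the
  loader by default (`allow_modifier_overlap` opts in); when allowed, it
  modifies its successor and scores itself.

## Pre-processing

Tokenization splits on Unicode letter runs, so punctuation, digits and
underscores never enter tokens and de-identification placeholders like
`(NAME-1)` are dropped beforehand as non-words.  Cleaning removes
stopwords, pure-number tokens, single-character tokens and tokens with
underscores — with the configured negators and intensifiers exempted from
stopword removal unconditionally, because silently deleting "niet" flips
downstream scores.  Stopword removal happens before n-gram formation, and
sentence boundaries are not marked (n-grams may cross them); both are
interpretive choices where the original tool's behaviour is unknown, and
are flagged as such.

The relevance filter excludes records with fewer than five cleaned tokens
or without any sentiment-bearing token.  The five-word rule is counted on
the cleaned stream, on the reading that the automated tool filtered after
its own pre-processing.

`pseudonymize` replaces identifying text with numbered placeholders
(`(NAME-k)`, `(DATE-k)`, `(AGE)`, `(LOCATION-k)`; e-mail/URL/phone/postal
deleted).  Name detection is a capitalization heuristic with a small
location gazetteer.  **It is a fixture convenience for shareable examples,
not a compliance-grade de-identification tool.**

## Calibration

Raw overall scores are z-standardized (sample SD, `ddof=1`; population SD
is a toggle) pooled over all relevant records across patients — pooling
chosen because per-patient series are plotted on a common standardized
scale.  The neutral band is data-driven: its bounds are the largest
strictly-negative and smallest strictly-positive standardized scores, so
the bounds are always members of the score set and exact zeros fall inside
the band.  Categorization is inclusive-neutral at the bounds ("negative"
and "positive" are strict inequalities).  Human 1–7 ratings categorize on
the raw scale (<4 / =4 / >4); the two raters' average (over records rated
by both) is standardized for the continuous per-patient series.  "Mixed"
(equal positive and negative content) is metadata on neutral ratings and
maps to neutral in every agreement statistic.

## Agreement estimators

**Weighted kappa.**  `κ_w = (P_o − P_e)/(1 − P_e)` over the ordered
categories negative < neutral < positive, with agreement weights
`w_ij = 1 − |i−j|/(C−1)` (linear, default), `1 − ((i−j)/(C−1))²`
(quadratic) or `δ_ij` (unweighted).  The choice of weights is consequential
— on the same 3×3 table the three schemes can differ by ~0.1 — and the
default is configurable because published analyses often omit the scheme.
The CI is `κ ± z_{1−α/2}·SE` with the Fleiss–Cohen–Everitt large-sample
SE; the estimator and SE are validated against statsmodels to machine
precision in the tests.

**ICC(A,1).**  From two-way single-observation ANOVA mean squares with
rows = subjects, columns = raters (k = 2):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

F = MSR/MSE on (n−1, (n−1)(k−1)) df; the CI is the McGraw–Wong F-based
interval with the Satterthwaite-style df `v` for the lower/upper bounds.
Degenerate cases: identical columns (MSE = MSC = 0) return estimate 1 with
a collapsed interval; all-equal input raises.  Missing values are handled
by pairwise deletion throughout (minimum 3 complete pairs).  Validated
against a loop-based sums-of-squares oracle (1e−10) and against pingouin.

Per-patient ICCs standardize both series on the pooled corpus first, then
restrict to each patient's jointly available records; patients under the
3-pair minimum are skipped.

## Synthetic data

**Corpus generator.**  Records are chains of insertion units — two filler
tokens, an optional modifier, a sentiment word — so every match's one- and
two-back context is controlled; fillers are verified disjoint from lexicon,
modifiers and the bundled stopword list.  Positive/negative records insert
1–4 units of the target sign (a negated unit pairs the negator with an
opposite-polarity word, keeping the net sign; an intensified unit doubles
it).  Neutral and mixed records insert balanced +/− pairs sharing one unit
style so contributions cancel exactly; match-free "neutral" records are not
generated because they would fail the relevance filter, whose "no sentiment
words" branch is exercised by the irrelevant component instead.  Irrelevant
records are either under five tokens or sentiment-free.  The generator
tracks each unit's bigram/trigram contribution in its own closed form and
records the exact expected overall score — an independent implementation of
the score semantics whose agreement with the scorer is the core
cross-validation (100% exact on default corpora; the only tolerated
divergence class would come from clamping, which the unit bookkeeping also
applies).

Defaults emulate the study conditions: 8 patients, 40–75 records each
(mean ≈ 57.5), category mix positive 0.25 / negative 0.29 / neutral 0.042 /
mixed 0.098 / irrelevant 0.32 — i.e. ~68.5% relevant, the relevant mass
split like the reported automated categories, and 70% of the neutral mass
flagged mixed.  Modifier rates (p_negation 0.15, p_intensifier 0.10) and
the context-word rate (0.05) are not reported anywhere and were fixed once
at values that make modified n-grams common enough to exercise every code
path while leaving most matches plain, as in ordinary prose.

**Rater simulator.**  `observed_r = latent + bias_r + ε_r` with the error
variance solving `ρ = σ²_L / (σ²_L + θ_C + σ²_E)` for the requested true
ICC, where `θ_C = (b₁−b₂)²/2` is the rater-bias (column) component;
infeasible bias/ICC combinations are rejected.  `latent_var` supplies the
known generating variance of the latent scores: recovery studies should
pass it so each replicate is an unconditional draw from the stated model —
deriving the noise from the realized sample variance instead (the default
for one-off use) conditions the replicate on the sample, shrinks estimator
spread and makes CI coverage look conservative.  Continuous scores are
discretized to 1–7 by fixed equal-width cuts at ±0.5, ±1.5, ±2.5 on the
latent (z-like) scale; discretization attenuates the ICC (≈0.85 observed
at ρ = 0.9 on the 7-point scale), which is why recovery checks run on the
continuous scores and the discrete ratings feed the categorical analyses.
Each rater independently abstains ("irrelevant") with probability
`p_irrelevant_disagree`, producing the missingness pattern that pairwise
deletion handles.

Measured under these conditions (500 replicates, n = 250): mean estimate
within 0.005 of ρ ∈ {0.3, 0.6, 0.9} and 95% CI coverage 0.94–0.956.

**What the synthetic data does not show.**  Generated records are token
mixtures, not Dutch clinical prose: no syntax, no misspellings, no implicit
sentiment, no clinician style variation, and sentiment words never appear
in uncontrolled adjacency.  Passing tests therefore demonstrate that the
pipeline computes its definitions correctly and that the estimators recover
known truth — not that the scorer reads real clinical notes as a human
would, which is precisely the empirical question such a validation study
asks of real data.

## Numerical conventions

- Displayed percentages round half-up to one decimal.
- Scorer arithmetic is exact in floating point for the integer n-gram
  scores; oracle-equivalence tests assert exact equality.
- Problem sizes in the test and acceptance runs (1000 random token lists,
  500 recovery replicates at n = 250, one default-size corpus) were chosen
  as the smallest sizes at which binomial/Monte-Carlo error is comfortably
  inside the asserted margins.
- Seeds are mandatory in all generator specs; nothing seeds from the
  wall clock.

## Known limitations

- Binary polarity only; no 0-polarity lexicon entries, no emotion
  categories, no syntax-aware negation scope.
- Two raters only (no Fleiss kappa / average-measure ICC variants).
- The de-identification pass is heuristic (see above).
- The neutral band depends on the corpus realization near zero and can be
  wide when few scores fall near zero (visible in the synthetic example);
  a manual band can be supplied where a study-fixed band is wanted.
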