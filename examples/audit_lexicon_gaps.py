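"""Find context-specific sentiment the lexicon misses or mislabels.

Domain word lists (here a small illustrative eating-disorder list) flag two
failure modes of a general-purpose lexicon: expressions it cannot see at
all ("herstellijn", recovery line) and words whose generic polarity is
wrong in context ("sporten" reads +1 generically but often signals
compensation behaviour).
"""

from pathlib import Path

import sentisess
from sentisess import default_stopwords, demo_lexicon, prepare_records, score_corpus
from sentisess.audit import load_context_words, missing_context_words, polarity_conflicts
from sentisess.preprocess import SessionRecord

lexicon = demo_lexicon()
context = load_context_words(
    Path(sentisess.__file__).parent / "data" / "demo_context.tsv"
)

notes = [
    SessionRecord("a1", "p1", 1, "Patiënt laat een mooie herstellijn zien deze periode."),
    SessionRecord("a2", "p1", 2, "Ging vandaag weer sporten ondanks het besproken plan."),
    SessionRecord("a3", "p1", 3, "De herstellijn zet door, patiënt is trots en gemotiveerd."),
]
prepared = prepare_records(notes, lexicon, default_stopwords(lexicon.modifiers))
results = score_corpus(prepared, lexicon)

print("context expressions invisible to the lexicon (expression, count):")
for expr, n in missing_context_words(prepared, lexicon, context):
    print(f"  {expr}: {n}")
print("\nlexicon/context polarity conflicts (word, lexicon, context, matches):")
for word, lex_pol, ctx_pol, n in polarity_conflicts(results, context):
    print(f"  {word}: lexicon {lex_pol:+d} vs context {ctx_pol:+d} ({n} match(es))")
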