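"""Score two short clinician-style notes with the bundled demo lexicon.

Each sentiment word's score is its lexicon polarity (+1/-1), inverted by a
preceding negator ("niet") and doubled by a preceding intensifier ("heel").
The record's overall score averages the bigram and trigram channel means
and lives in [-1, 1]; records under five words or without sentiment words
are filtered out as irrelevant.
"""

from sentisess import demo_lexicon, default_stopwords, prepare_records, score_record
from sentisess.audit import match_report
from sentisess.preprocess import SessionRecord

lexicon = demo_lexicon()
stop = default_stopwords(lexicon.modifiers)

notes = [
    SessionRecord("n1", "p1", 1, "Patiënt voelt zich vandaag niet goed en erg somber."),
    SessionRecord("n2", "p1", 2, "Gesprek verliep prima, patiënt was heel trots op de vooruitgang."),
    SessionRecord("n3", "p1", 3, "Afspraak verzet."),  # too short -> irrelevant
]

for rec in prepare_records(notes, lexicon, stop):
    res = score_record(rec, lexicon)
    print(f"\n{rec.record_id}: {rec.text!r}")
    print(f"  tokens: {list(rec.tokens)}")
    if not res.relevant_auto:
        print("  -> excluded by the relevance filter (<5 words or no sentiment words)")
        continue
    print(match_report(res).to_string(index=False))
    print(f"  bigram mean {res.bigram_final:+.2f}, trigram mean {res.trigram_final:+.2f}"
          f" -> overall {res.overall:+.2f}")
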