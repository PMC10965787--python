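# Small Dutch stopword list for docs and tests.
# The preprocessing pipeline exempts configured negators/intensifiers
# from stopword removal regardless of this list's contents.
de
het
een
en
van
ik
je
dat
is
in
te
met
op
voor
zijn
was
aan
er
maar
om
ook
als
bij
dan
uit
naar
door
over
zo
wat
mijn
dit
deze
hij
zij
we
wordt
werd
heeft
had
hebben
worden
al
nog
wel
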