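# Synthetic stand-in for a context-specific eating-disorder sentiment word list.
# Columns: expression (1-3 tokens)	polarity	context label
# These entries are illustrative fixtures, not a curated clinical resource.
herstellijn	+1	ED
mooie herstellijn	+1	ED
ruimte innemen	+1	AN
meer voelen	+1	ED
hersteldoel	+1	ED
eetmoment gelukt	+1	ED
sporten	-1	AN
compenseren	-1	AN
lichaamsbeleving	-1	ED
emotieregulatie	-1	ED
eetbui	-1	BED
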