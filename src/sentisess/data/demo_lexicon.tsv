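# Demo Dutch polarity lexicon for docs and tests only.
# Real analyses require user-supplied lexicons.
word	polarity
goed	+1
blij	+1
fijn	+1
rustig	+1
trots	+1
sterk	+1
gelukkig	+1
positief	+1
vooruitgang	+1
hoop	+1
gemotiveerd	+1
tevreden	+1
ontspannen	+1
vrolijk	+1
succes	+1
beter	+1
genieten	+1
energie	+1
zelfvertrouwen	+1
stabiel	+1
sporten	+1
slecht	-1
verdrietig	-1
angstig	-1
boos	-1
somber	-1
moe	-1
gespannen	-1
negatief	-1
terugval	-1
paniek	-1
onrustig	-1
schuldig	-1
eenzaam	-1
wanhopig	-1
pijn	-1
moeilijk	-1
zwaar	-1
bang	-1
stress	-1
huilen	-1
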