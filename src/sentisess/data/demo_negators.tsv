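# Demo Dutch negators (invert the following sentiment word).
niet
geen
nooit
niets
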