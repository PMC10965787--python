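# Demo Dutch intensifiers / reinforcers (double the following sentiment word).
heel
zeer
extreem
ontzettend
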