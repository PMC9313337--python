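source	target	interaction	source_compartment	target_compartment	provenance
A	C	activation	cytoplasm	cytoplasm	original
A	B	activation	cytoplasm	cytoplasm	original
D	A	inhibition	nucleus	cytoplasm	original
B	D	activation	cytoplasm	nucleus	original
C	D	activation	cytoplasm	nucleus	original
E	D	expression	nucleus	nucleus	original
D	E	activation	nucleus	nucleus	original
E	F	activation	nucleus	cytoplasm	original
E	G	activation	nucleus	cytoplasm	original
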