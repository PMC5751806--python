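pattern	label_type	value_or_capture	confidence
male	sex	male	1.0
m	sex	male	1.0
man	sex	male	1.0
female	sex	female	1.0
f	sex	female	1.0
woman	sex	female	1.0
1	sex	male	0.5
0	sex	female	0.5
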