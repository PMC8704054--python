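# approximate helical-segment annotation for CXCR5 (P32302)
NTERM	NTERM	1	52
TM1	TM	53	81
ICL1	ICL	82	84
TM2	TM	85	113
ECL1	ECL	114	131
TM3	TM	132	159
TM4	TM	160	186
ECL2	ECL	187	218
TM5	TM	219	247
ICL3	ICL	248	256
TM6	TM	257	285
ECL3	ECL	286	300
TM7	TM	301	329
CTERM	CTERM	330	372
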