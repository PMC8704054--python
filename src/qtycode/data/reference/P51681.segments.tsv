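# approximate helical-segment annotation for CCR5 (P51681)
NTERM	NTERM	1	32
TM1	TM	33	61
TM2	TM	62	90
ECL1	ECL	91	100
TM3	TM	101	129
ICL2	ICL	130	141
TM4	TM	142	170
ECL2	ECL	171	189
TM5	TM	190	218
ICL3	ICL	219	233
TM6	TM	234	262
ECL3	ECL	263	281
TM7	TM	282	310
CTERM	CTERM	311	352
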