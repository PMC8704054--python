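# approximate helical-segment annotation for CXCR4 (P61073)
NTERM	NTERM	1	38
TM1	TM	39	67
ICL1	ICL	68	76
TM2	TM	77	105
ECL1	ECL	106	108
TM3	TM	109	137
ICL2	ICL	138	149
TM4	TM	150	178
ECL2	ECL	179	198
TM5	TM	199	227
ICL3	ICL	228	237
TM6	TM	238	266
ECL3	ECL	267	281
TM7	TM	282	310
CTERM	CTERM	311	352
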