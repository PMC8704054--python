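# approximate helical-segment annotation for ACKR3 (P25106)
NTERM	NTERM	1	36
TM1	TM	37	65
ICL1	ICL	66	81
TM2	TM	82	110
ECL1	ECL	111	116
TM3	TM	117	145
ICL2	ICL	146	153
TM4	TM	154	182
ECL2	ECL	183	211
TM5	TM	212	240
ICL3	ICL	241	252
TM6	TM	253	281
ECL3	ECL	282	293
TM7	TM	294	322
CTERM	CTERM	323	362
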