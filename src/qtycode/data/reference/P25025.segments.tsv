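# approximate helical-segment annotation for CXCR2 (P25025)
NTERM	NTERM	1	50
TM1	TM	51	79
TM2	TM	80	108
ECL1	ECL	109	127
TM3	TM	128	156
ICL2	ICL	157	158
TM4	TM	159	187
ECL2	ECL	188	211
TM5	TM	212	240
ICL3	ICL	241	246
TM6	TM	247	275
ECL3	ECL	276	294
TM7	TM	295	323
CTERM	CTERM	324	359
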