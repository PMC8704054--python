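# approximate helical-segment annotation for OR1D2 (P34982)
NTERM	NTERM	1	25
TM1	TM	26	53
TM2	TM	54	80
ECL1	ECL	81	95
TM3	TM	96	124
ICL2	ICL	125	134
TM4	TM	135	163
ECL2	ECL	164	193
TM5	TM	194	222
ICL3	ICL	223	233
TM6	TM	234	262
ECL3	ECL	263	268
TM7	TM	269	297
CTERM	CTERM	298	312
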