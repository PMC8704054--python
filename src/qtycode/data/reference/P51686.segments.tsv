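# approximate helical-segment annotation for CCR9 (P51686)
NTERM	NTERM	1	48
TM1	TM	49	77
ICL1	ICL	78	84
TM2	TM	85	113
ECL1	ECL	114	124
TM3	TM	125	153
ICL2	ICL	154	161
TM4	TM	162	190
ECL2	ECL	191	214
TM5	TM	215	243
ICL3	ICL	244	251
TM6	TM	252	280
ECL3	ECL	281	297
TM7	TM	298	326
CTERM	CTERM	327	369
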