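# approximate helical-segment annotation for CCR10 (P46092)
NTERM	NTERM	1	41
TM1	TM	42	70
ICL1	ICL	71	75
TM2	TM	76	104
ECL1	ECL	105	110
TM3	TM	111	139
ICL2	ICL	140	154
TM4	TM	155	183
ECL2	ECL	184	206
TM5	TM	207	235
ICL3	ICL	236	242
TM6	TM	243	271
ECL3	ECL	272	288
TM7	TM	289	317
CTERM	CTERM	318	362
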