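# accession	name
P51681	CCR5
P61073	CXCR4
P51686	CCR9
P25025	CXCR2
P46092	CCR10
P32302	CXCR5
P25106	ACKR3
P34982	OR1D2
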