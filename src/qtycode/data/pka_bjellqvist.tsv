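# Bjellqvist pKa set as deployed by the Expasy Compute pI/MW service.
# group	key	pka
cterm	default	3.55
cterm	D	4.55
cterm	E	4.75
nterm	default	7.50
nterm	A	7.59
nterm	M	7.00
nterm	S	6.93
nterm	P	8.36
nterm	T	6.82
nterm	V	7.44
nterm	E	7.70
side	C	9.00
side	D	4.05
side	E	4.45
side	H	5.98
side	K	10.00
side	R	12.00
side	Y	10.00
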