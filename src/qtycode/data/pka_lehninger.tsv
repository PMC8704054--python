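# Classic textbook (Lehninger) pKa set; alternative to the Bjellqvist default.
# group	key	pka
cterm	default	3.10
nterm	default	8.00
side	C	8.18
side	D	3.65
side	E	4.25
side	H	6.00
side	K	10.53
side	R	12.48
side	Y	10.07
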