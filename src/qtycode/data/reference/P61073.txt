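ID   CXCR4_HUMAN             Reviewed;         352 AA.
AC   P61073;
DE   RecName: Full=C-X-C chemokine receptor type 4;
FT   TRANSMEM        39..67
FT                   /note="Helical"
FT   TRANSMEM        77..105
FT                   /note="Helical"
FT   TRANSMEM        109..137
FT                   /note="Helical"
FT   TRANSMEM        150..178
FT                   /note="Helical"
FT   TRANSMEM        199..227
FT                   /note="Helical"
FT   TRANSMEM        238..266
FT                   /note="Helical"
FT   TRANSMEM        282..310
FT                   /note="Helical"
SQ   SEQUENCE   352 AA;  40000 MW;  0000000000000000 CRC64;
     MEGISIYTSD NYTEEMGSGD YDSMKEPCFR EENANFNKIF LPTIYSIIFL TGIVGNGLVI
     LVMGYQKKLR SMTDKYRLHL SVADLLFVIT LPFWAVDAVA NWYFGNFLCK AVHVIYTVNL
     YSSVLILAFI SLDRYLAIVH ATNSQRPRKL LAEKVVYVGV WIPALLLTIP DFIFANVSEA
     DDRYICDRFY PNDLWVVVFQ FQHIMVGLIL PGIVILSCYC IIISKLSHSK GHQKRKALKT
     TVILILAFFA CWLPYYIGIS IDSFILLEII KQGCEFENTV HKWISITEAL AFFHCCLNPI
     LYAFLGAKFK TSAQHALTSV SRGSSLKILS KGKRGGHSSV STESESSSFH SS
//
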