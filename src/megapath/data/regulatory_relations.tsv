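# Synthetic stand-in for the regulator->disease-driver worksheet rows:
# 7 disease promoters deactivated and 3 disease inhibitors activated by the
# regulator.  EDN1 is used where the source text prints "END1" (a likely
# typo for endothelin 1).  Four genes (IL1B, PTGS2, TNF, MIR145) also appear
# in the common-target table, so the union of driven molecules is 25.
regulator	target	polarity	disease_direction	n_refs
PPARG	IL1B	-|	promoter	17
PPARG	PTGS2	-|	promoter	23
PPARG	EDN1	-|	promoter	6
PPARG	TNF	-|	promoter	28
PPARG	CCR7	-|	promoter	4
PPARG	TLR2	-|	promoter	5
PPARG	NFKB1	-|	promoter	15
PPARG	MIR145	-+>	inhibitor	12
PPARG	IL10	-+>	inhibitor	9
PPARG	ADIPOQ	-+>	inhibitor	7
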