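# Synthetic stand-in for the literature worksheet of PPARG/lung-adenocarcinoma
# common targets: 13 disease-upregulated genes under negative regulation and
# 6 disease-downregulated genes under positive regulation.  Gene names beyond
# those reported in the source literature are plausible placeholders.
regulator	target	polarity	disease_direction	n_refs
PPARG	COL1A1	-|	up_in_disease	14
PPARG	SPP1	-|	up_in_disease	9
PPARG	CXCL14	-|	up_in_disease	4
PPARG	MMP9	-|	up_in_disease	21
PPARG	CCNB1	-|	up_in_disease	6
PPARG	IL1B	-|	up_in_disease	17
PPARG	PTGS2	-|	up_in_disease	23
PPARG	TNF	-|	up_in_disease	28
PPARG	MMP2	-|	up_in_disease	11
PPARG	VEGFA	-|	up_in_disease	19
PPARG	CCND1	-|	up_in_disease	13
PPARG	MYC	-|	up_in_disease	8
PPARG	TERT	-|	up_in_disease	3
PPARG	CAV1	-+>	down_in_disease	7
PPARG	PTEN	-+>	down_in_disease	16
PPARG	FAS	-+>	down_in_disease	5
PPARG	MIR145	-+>	down_in_disease	12
PPARG	CDH1	-+>	down_in_disease	6
PPARG	TP53	-+>	down_in_disease	10
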