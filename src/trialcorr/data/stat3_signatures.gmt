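STAT3_SIGNATURE_A	placeholder pathway gene set A (editable; substitute published list)	SOCS3	EGFR	BCL3	JUNB	MYC	OSMR	IL6R	PIM1	CCND1	MCL1	BCL2L1	VEGFA
STAT3_SIGNATURE_B	placeholder pathway gene set B (editable; substitute published list)	SOCS3	STAT3	JAK2	IL6ST	FOS	HIF1A	ICAM1	MMP9	PTGS2	CDKN1A	SERPINA3	TIMP1
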