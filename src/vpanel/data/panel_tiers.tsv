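# Top two tiers of the published virtual panel generated for the index case
# (query: ataxia, seizures, esotropia, puberty and gonadal disorders, global
# developmental delay, autosomal recessive inheritance). Gene symbols are
# transcribed as printed, including the source's apparent typos (K1F1A,
# C100RF2). Lower tiers (counts 3/2/1) depend on the annotation snapshot of
# the era and are not reproduced.
tier	gene
6	PMM2
6	CEP290
5	GBA
5	POLG
5	GP1BB
5	HSD17B4
5	PEX1
5	PEX6
5	ERCC2
5	BCS1L
5	DOCK8
5	PEX10
5	TCF4
5	PEX12
5	ERCC6
5	RRM2B
5	PEX26
5	PEX2
5	ERCC4
5	PEX16
5	GRIN2B
5	PEX5
5	ERCC1
5	WDR73
5	PEX3
5	K1F1A
5	PEX14
5	PEX19
5	PEX11B
5	ADGRG1
5	C100RF2
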