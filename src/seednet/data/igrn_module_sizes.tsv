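module	submodule	n_genes
CCR5	CCR5	176
CCR5	CD2	87
CCR5	IGLC2	39
CCR5	IFI44L	31
CCR5	PSMB9	21
CCR5	CXCL10	9
CCR5	HLA-DRA	5
CCR5	ABI3	2
CCR5	CARD16	2
CCR5	FTL	2
CCR5	TRIM22	2
SPARC	SPARC	152
SPARC	LDB2	41
SPARC	ABCA8	8
SPARC	TMEM204	8
SPARC	SPARCL1	7
SPARC	CNRIP1	6
SPARC	VIM	4
SPARC	CARD6	2
SPARC	DZIP1	2
ZFPM1	ZFPM1	71
ZFPM1	EXOC3L2	58
ZFPM1	JSRP1	22
ZFPM1	GUCA2A	13
ZFPM1	LILRB3	4
ZFPM1	ATXNL2	2
ZFPM1	CGB2	2
ZFPM1	ZNF683	1
ACSL4	-	8
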