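FERROPTOSIS_DRIVER	synthetic stand-in for a curated ferroptosis driver gene list	ACSL4	LPCAT3	ALOX15	ALOX12	ALOX5	POR	TFRC	NCOA4	ATG5	ATG7	SAT1	TP53	HMOX1	CYBB	NOX1	DPP4	GLS2	CARS1	ELAVL1	BAP1
FERROPTOSIS_SUPPRESSOR	synthetic stand-in for a curated ferroptosis suppressor gene list	GPX4	SLC7A11	SLC3A2	AIFM2	FTH1	FTL	NFE2L2	HSPB1	SCD	ACSL3	FADS2	CBS	CA9	PROM2	SREBF2	SQLE	MUC1	OTUB1	PRDX6	GCH1
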