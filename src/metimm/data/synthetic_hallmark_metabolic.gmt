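GLYCOLYSIS_CANDIDATES	synthetic stand-in for a hallmark glycolysis gene list	ALDOA	ALDOB	ALDOC	PFKL	PFKM	PFKP	PKM	PGK1	PGAM1	ENO1	ENO2	GAPDH	HK1	HK2	HK3	GPI	TPI1	LDHA	LDHB	SLC2A1	SLC2A3	SLC16A3	PDK1	PDK3	PGM1	PGM2	GALK1	GALK2	FBP1	FBP2	GYS1	PYGB	PYGL	UGP2	G6PD	TALDO1	TKT	PRPS1	DLD	ME2
CHOLESTEROL_CANDIDATES	synthetic stand-in for a hallmark cholesterol biosynthesis gene list	HMGCR	HMGCS1	MVK	PMVK	MVD	IDI1	FDPS	FDFT1	SQLE	LSS	CYP51A1	MSMO1	NSDHL	SC5D	DHCR7	DHCR24	EBP	TM7SF2	SREBF2	INSIG1	LDLR	ACAT2	PCSK9	SCD	STARD4	SOAT1
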