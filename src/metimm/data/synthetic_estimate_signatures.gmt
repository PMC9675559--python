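ESTIMATE_STROMAL	synthetic stand-in for the stromal signature gene list	COL1A1	COL1A2	COL3A1	COL5A1	FAP	FN1	THBS2	POSTN	DCN	LUM	FBLN1	ACTA2	PDGFRA	PDGFRB	TAGLN	MYL9	SPARC	VIM	ZEB1	TWIST1	SNAI2	MMP2	TIMP2	CDH11	OLFML2B	ISLR	GREM1	SFRP2	SFRP4	ASPN	OGN	VCAN
ESTIMATE_IMMUNE	synthetic stand-in for the immune signature gene list	PTPRC	CD2	CD3D	CD3E	CD3G	CD4	CD8B	CD19	MS4A1	CD79A	CD79B	IL7R	CCL19	CCL21	CXCL13	CD52	LTB	SELL	CCR7	GZMA	GZMB	GZMK	PRF1	KLRB1	KLRD1	CST7	LAPTM5	SRGN	CD48	CD53	IL2RG	TRAC
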