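aDCs	synthetic stand-in immune signature	CCL1	EBI3	IDO1	LAMP3	OAS3	INDO
APC_co_inhibition	synthetic stand-in immune signature	CD274	PDCD1LG2	VTCN1	LGALS9	HHLA2
APC_co_stimulation	synthetic stand-in immune signature	CD40	CD58	CD70	CD80	CD86	ICOSLG	TNFSF9
B_cells	synthetic stand-in immune signature	CD19	MS4A1	CD79A	CD79B	BLK	FCRL2	TNFRSF17
CCR	synthetic stand-in immune signature	CCR1	CCR2	CCR4	CCR5	CCR6	CXCR3	CXCR4
CD8_T_cells	synthetic stand-in immune signature	CD8A	CD8B	GZMM	FLT3LG	PRF1	ZEB1
Checkpoint	synthetic stand-in immune signature	PDCD1	CTLA4	LAG3	TIGIT	HAVCR2	BTLA	IDO1
Cytolytic_activity	synthetic stand-in immune signature	GZMA	PRF1	GZMH	GNLY	KLRK1
DCs	synthetic stand-in immune signature	CCL13	CD209	HSD11B1	NPR1	PPFIBP2
HLA	synthetic stand-in immune signature	HLA-A	HLA-B	HLA-C	HLA-DQA1	HLA-DRB1	HLA-E	HLA-F
iDCs	synthetic stand-in immune signature	CD1A	CD1B	CD1E	F13A1	SYT17	MMP12
Inflammation_promoting	synthetic stand-in immune signature	IL1A	IL1B	IL6	CXCL8	PTGS2	TNF
Macrophages	synthetic stand-in immune signature	CD68	CD163	MSR1	MRC1	SIGLEC1	VSIG4
Mast_cells	synthetic stand-in immune signature	TPSAB1	TPSB2	CPA3	MS4A2	HDC	CMA1
MHC_class_I	synthetic stand-in immune signature	B2M	TAP1	TAP2	TAPBP	NLRC5
Neutrophils	synthetic stand-in immune signature	FCGR3B	CSF3R	CEACAM3	S100A12	FPR1	SIGLEC5
NK_cells	synthetic stand-in immune signature	KIR2DL1	KIR2DL3	KIR3DL1	NCR1	XCL1	XCL2
Parainflammation	synthetic stand-in immune signature	AIM2	CCND1	PLAT	MX1	ISG15	SELE
pDCs	synthetic stand-in immune signature	IL3RA	CLEC4C	LILRA4	GZMB	IRF7
T_cell_co_inhibition	synthetic stand-in immune signature	PDCD1	CD160	CD244	LAIR1	TIGIT	CTLA4
T_cell_co_stimulation	synthetic stand-in immune signature	CD28	ICOS	TNFRSF9	TNFRSF18	CD226	SLAMF1
T_helper_cells	synthetic stand-in immune signature	CD4	IL7R	CD40LG	ANP32B	ASF1A	BATF
Tfh	synthetic stand-in immune signature	CXCL13	CXCR5	ICOS	PDCD1	BCL6	IL21
Th1_cells	synthetic stand-in immune signature	TBX21	IFNG	IL12RB2	STAT4	CCL4	IL2
Th2_cells	synthetic stand-in immune signature	GATA3	IL4	IL5	IL13	CCR3	STAT6
TIL	synthetic stand-in immune signature	CD3D	CD3E	CD2	TRAC	TRBC1	CD52
Treg	synthetic stand-in immune signature	FOXP3	IL2RA	IKZF2	CCR8	TNFRSF4
Type_I_IFN_response	synthetic stand-in immune signature	IFIT1	IFIT3	IFI44	MX1	MX2	OAS1	RSAD2
Type_II_IFN_response	synthetic stand-in immune signature	IFNG	CXCL9	CXCL10	CXCL11	IDO1	GBP1
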