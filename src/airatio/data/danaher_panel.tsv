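cell_type	gene	compartment
B-cells	BLK	adaptive
B-cells	CD19	adaptive
B-cells	FCRL2	adaptive
B-cells	KIAA0125	adaptive
B-cells	MS4A1	adaptive
B-cells	PNOC	adaptive
B-cells	SPIB	adaptive
B-cells	TCL1A	adaptive
B-cells	TNFRSF17	adaptive
CD45	PTPRC	adaptive
CD8 T-cells	CD8A	adaptive
CD8 T-cells	CD8B	adaptive
Cytotoxic cells	CTSW	adaptive
Cytotoxic cells	GNLY	adaptive
Cytotoxic cells	GZMA	adaptive
Cytotoxic cells	GZMB	adaptive
Cytotoxic cells	GZMH	adaptive
Cytotoxic cells	KLRB1	adaptive
Cytotoxic cells	KLRD1	adaptive
Cytotoxic cells	KLRK1	adaptive
Cytotoxic cells	NKG7	adaptive
Cytotoxic cells	PRF1	adaptive
T-cells	CD3D	adaptive
T-cells	CD3E	adaptive
T-cells	CD3G	adaptive
T-cells	CD6	adaptive
T-cells	SH2D1A	adaptive
T-cells	TRAT1	adaptive
Th1 cells	TBX21	adaptive
Treg	FOXP3	adaptive
Dendritic cells	CCL13	innate
Dendritic cells	CD209	innate
Dendritic cells	HSD11B1	innate
Macrophages	CD163	innate
Macrophages	CD68	innate
Macrophages	CD84	innate
Macrophages	MS4A4A	innate
Mast cells	CPA3	innate
Mast cells	HDC	innate
Mast cells	MS4A2	innate
Mast cells	TPSAB1	innate
Mast cells	TPSB2	innate
Neutrophils	CEACAM3	innate
Neutrophils	CSF3R	innate
Neutrophils	FCAR	innate
Neutrophils	FCGR3B	innate
Neutrophils	FPR1	innate
Neutrophils	S100A12	innate
Neutrophils	SIGLEC5	innate
NK cells	NCR1	innate
NK cells	XCL1	innate
NK cells	XCL2	innate
NK CD56dim cells	IL21R	innate
NK CD56dim cells	KIR2DL3	innate
NK CD56dim cells	KIR3DL1	innate
NK CD56dim cells	KIR3DL2	innate
Exhausted CD8	CD244	excluded
Exhausted CD8	EOMES	excluded
Exhausted CD8	LAG3	excluded
Exhausted CD8	PTGER4	excluded
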