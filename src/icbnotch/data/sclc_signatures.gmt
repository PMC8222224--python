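NE_HIGH	neuroendocrine-high SCLC markers (test-scale list)	ASCL1	INSM1	CHGA	SYP	NCAM1	GRP	DDC	CALCA	SCG3	CHGB	UCHL1	BEX1
NE_LOW	low-neuroendocrine / non-NE SCLC markers (test-scale list)	YAP1	VIM	MYOF	CAV1	CAV2	ANXA1	S100A10	ITGB4	EPHA2	AHNAK	CCN1	TACSTD2
NOTCH_SIGNALING	Notch pathway receptors, targets and effectors (test-scale list)	NOTCH1	NOTCH2	NOTCH3	HES1	HEY1	HEYL	REST	JAG1	DLL1	MAML2	ADAM10	RBPJ
IMMUNE_SIGNATURE	T-cell and cytokine immune markers (test-scale list)	CD3E	CD8A	CD4	CCL5	CXCL9	CXCL10	GZMB	PRF1	IFNG	PDCD1	CD274	CTLA4
ANTIGEN_PRESENTATION	MHC class I antigen processing and presentation machinery (test-scale list)	B2M	TAP1	TAP2	PSMB8	PSMB9	HLA-A	HLA-B	HLA-C	NLRC5	ERAP1
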