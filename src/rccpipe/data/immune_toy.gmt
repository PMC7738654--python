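TOY_MHC_BINDING	synthetic toy term	TAPBP	TAP2	PSMB9	PSMB10	BCAP31	LAG3	CD4	CD8A
TOY_CYTOKINE_BINDING	synthetic toy term	TNF	IL16	IL2RG	IL21R	EBI3	SOCS3	STAT1	STAT3
TOY_TNF_RECEPTOR_BINDING	synthetic toy term	TNF	TNFRSF1B	TNFRSF14	TRAF2	FADD	LTBR	TNFSF4
TOY_CHEMOKINE_ACTIVITY	synthetic toy term	CXCL1	CXCL2	CXCL11	CXCR3	CXCR4	CCR2	CCR6
TOY_LYMPHOCYTE_ACTIVATION	synthetic toy term	LCK	CD3D	CD27	CD40	ITGAL	ITGB2	ZAP70	PRF1	GZMA	GZMK
TOY_COMPLEMENT_LIKE	synthetic toy term	C7	CD59	CD9	CD36	PECAM1	NT5E
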