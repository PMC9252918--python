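PI	reconstructed 11-gene proliferation panel	BIRC5	CCNB1	CKS1B	MKI67	PCLAF	TK1	TOP2A	TRIP13	TYMS	UBE2C	ZWINT
CGA	reconstructed 27 hematological cancer germline antigens	CTAG1B	CTAG2	GAGE1	GAGE2A	GAGE12F	MAGEA1	MAGEA3	MAGEA4	MAGEA6	MAGEA10	MAGEA12	MAGEB1	MAGEB2	MAGEC1	MAGEC2	CT45A1	CT47A11	CT83	PASD1	PRAME	SAGE1	SPANXB1	SSX1	SSX2	SSX4	LIN28B	PAGE2
NFKB_index	reconstructed NFkB activity index	BIRC3	CD74	IL2RG	MALT1	NFKB2	NFKBIA	NFKBIE	PLEK	RELB	TNFAIP3	WNT10A
HLA_I	reconstructed MHC class I score	B2M	HLA-A	HLA-B	HLA-C	HLA-E	HLA-F	NLRC5	TAP1	TAP2	TAPBP
HLA_II	reconstructed MHC class II score	CD74	CIITA	HLA-DMA	HLA-DMB	HLA-DOA	HLA-DOB	HLA-DPA1	HLA-DPB1	HLA-DQA1	HLA-DQB1	HLA-DRA	HLA-DRB1
ABC_transporters	ABC transporter drug-efflux panel	ABCA1	ABCB1	ABCB4	ABCC1	ABCC3	ABCC4	ABCC5	ABCG1	ABCG2
Exportins	nuclear exportin panel	XPO1	XPO4	XPO5	XPO6	XPO7	XPOT	CSE1L
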