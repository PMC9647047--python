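pair_id	gene_a	gene_b	coefficient
CD79A|RGS16	CD79A	RGS16	-0.0481033
CD79A|MZB1	CD79A	MZB1	-0.1940487
MS4A1|VPREB3	MS4A1	VPREB3	-0.0761894
BANK1|VPREB3	BANK1	VPREB3	0.1293327
ID3|HERPUD1	ID3	HERPUD1	0.0590669
CCR7|SPAG4	CCR7	SPAG4	-0.0987176
CD69|SPAG4	CD69	SPAG4	-0.1857905
HERPUD1|GADD45B	HERPUD1	GADD45B	-0.1646793
BHLHE41|TNFRSF17	BHLHE41	TNFRSF17	0.035946
H2AFZ|SSR4	H2AFZ	SSR4	0.1132622
TUBA1B|PRDX4	TUBA1B	PRDX4	0.0671402
BIRC3|LTB	BIRC3	LTB	0.0749648
BIRC3|IRF8	BIRC3	IRF8	0.0622839
BIRC3|RGS16	BIRC3	RGS16	0.2188708
BIRC3|SEC11C	BIRC3	SEC11C	0.1388304
BIRC3|NUCB2	BIRC3	NUCB2	0.0500247
IFT57|MYC	IFT57	MYC	-0.149355
IFT57|RGS16	IFT57	RGS16	-0.1944459
GADD45B|PIM2	GADD45B	PIM2	0.1640718
HES1|ITM2C	HES1	ITM2C	-0.3062981
MYC|PRDX4	MYC	PRDX4	0.13737
IRF8|SPAG4	IRF8	SPAG4	-0.1565463
RGS16|MZB1	RGS16	MZB1	0.0361053
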