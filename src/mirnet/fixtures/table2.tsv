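mirna	aliases	mirna_direction	gene	gene_direction
hsa-miR-1/206	hsa-miR-1;hsa-miR-206	up	API5	down
hsa-miR-1/206	hsa-miR-1;hsa-miR-206	up	PCDH17	down
hsa-miR-1/206	hsa-miR-1;hsa-miR-206	up	SMAD2	down
hsa-miR-1/206	hsa-miR-1;hsa-miR-206	up	MTSS1	down
hsa-miR-1/206	hsa-miR-1;hsa-miR-206	up	PDCD10	down
hsa-miR-1/206	hsa-miR-1;hsa-miR-206	up	PDCD4	down
hsa-miR-1/206	hsa-miR-1;hsa-miR-206	up	SMAD4	down
hsa-miR-141	hsa-miR-141	up	PDCD4	down
hsa-miR-141	hsa-miR-141	up	MTSS1	down
hsa-miR-141	hsa-miR-141	up	ARHGAP24	down
hsa-miR-141	hsa-miR-141	up	SIAH1	down
hsa-miR-141	hsa-miR-141	up	PTEN	down
hsa-miR-149	hsa-miR-149	up	TP63	down
hsa-miR-149	hsa-miR-149	up	SMAD2	down
hsa-miR-149	hsa-miR-149	up	CNTNAP2	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	DICER1	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	GIGYF2	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	STK4	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	RABGAP1	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	NOTCH2	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	NEDD9	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	ATM	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	SMAD2	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	NAV1	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	FOSL2	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	CAMKK2	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	STK4	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	BTG3	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	UBE2Z	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	IRF2	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	LIN54	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	HIF1A	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	RABGAP1	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	CCDC88A	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	ETV6	down
hsa-miR-18a/b	hsa-miR-18a;hsa-miR-18b	up	CCND2	down
hsa-miR-205	hsa-miR-205	up	CADM1	down
hsa-miR-205	hsa-miR-205	up	MORF4L2	down
hsa-miR-205	hsa-miR-205	up	PTEN	down
hsa-miR-205	hsa-miR-205	up	SMAD1	down
hsa-miR-205	hsa-miR-205	up	SMAD4	down
hsa-miR-205	hsa-miR-205	up	TP53BP2	down
hsa-miR-544	hsa-miR-544	up	AKT2	down
hsa-miR-544	hsa-miR-544	up	CADM1	down
hsa-miR-544	hsa-miR-544	up	CDH1	down
hsa-miR-544	hsa-miR-544	up	SMAD4	down
hsa-miR-99a/b	hsa-miR-99a;hsa-miR-99b	up	BMPR2	down
hsa-miR-99a/b	hsa-miR-99a;hsa-miR-99b	up	IGF1R	down
hsa-miR-99a/b	hsa-miR-99a;hsa-miR-99b	up	THAP2	down
hsa-miR-203	hsa-miR-203	down	BCL2L2	up
hsa-miR-203	hsa-miR-203	down	ESR1	up
hsa-miR-203	hsa-miR-203	down	HBEGF	up
hsa-miR-203	hsa-miR-203	down	HBP1	up
hsa-miR-203	hsa-miR-203	down	HSPB8	up
hsa-miR-203	hsa-miR-203	down	IGFBP5	up
hsa-miR-203	hsa-miR-203	down	ITGA2	up
hsa-miR-203	hsa-miR-203	down	LPP	up
hsa-miR-203	hsa-miR-203	down	MAP3K1	up
hsa-miR-203	hsa-miR-203	down	MKL2	up
hsa-miR-203	hsa-miR-203	down	MLLT4	up
hsa-miR-203	hsa-miR-203	down	SOCS3	up
hsa-miR-222	hsa-miR-222	down	ESR1	up
hsa-miR-222	hsa-miR-222	down	ITGB8	up
hsa-miR-222	hsa-miR-222	down	MBD2	up
hsa-miR-222	hsa-miR-222	down	MIA3	up
hsa-miR-222	hsa-miR-222	down	MLL	up
hsa-miR-222	hsa-miR-222	down	SOCS3	up
hsa-miR-222	hsa-miR-222	down	TET2	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	BCL2L2	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	HBEGF	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	HBP1	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	HSPG2	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	ITGB1	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	LAMC2	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	LTBR	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	MIB1	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	MLF1	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	MMP2	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	NDST1	up
hsa-miR-29a/c	hsa-miR-29a;hsa-miR-29c	down	SVEP1	up
hsa-miR-34b	hsa-miR-34b	down	BTRC	up
hsa-miR-34b	hsa-miR-34b	down	CTNNA1	up
hsa-miR-34b	hsa-miR-34b	down	CUL3	up
hsa-miR-34b	hsa-miR-34b	down	CYLD	up
hsa-miR-34b	hsa-miR-34b	down	ESR1	up
hsa-miR-34b	hsa-miR-34b	down	HIPK1	up
hsa-miR-34b	hsa-miR-34b	down	ITGA2	up
hsa-miR-34b	hsa-miR-34b	down	ITM2B	up
hsa-miR-34b	hsa-miR-34b	down	MKL2	up
hsa-miR-34b	hsa-miR-34b	down	MXD1	up
hsa-miR-34b	hsa-miR-34b	down	PAPD5	up
hsa-miR-34b	hsa-miR-34b	down	PPP1CB	up
hsa-miR-34b	hsa-miR-34b	down	SMAD3	up
hsa-miR-34c-3p	hsa-miR-34c-3p	down	DCBLD2	up
hsa-miR-34c-3p	hsa-miR-34c-3p	down	FOXN3	up
hsa-miR-34c-3p	hsa-miR-34c-3p	down	IKZF1	up
hsa-miR-34c-3p	hsa-miR-34c-3p	down	NPTN	up
hsa-miR-34c-3p	hsa-miR-34c-3p	down	PAFAH1B1	up
hsa-miR-34c-3p	hsa-miR-34c-3p	down	USP10	up
hsa-miR-34c-3p	hsa-miR-34c-3p	down	YY1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	ARHGAP1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	ARHGEF3	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	BCL11B	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	C16orf5	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	CNTNAP1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	FOXN3	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	FUT8	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	IL6R	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	ITGB8	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	ITSN1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	JAG1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	MLL2	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	NDST1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	NOTCH2	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	NPNT	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	PPFIA1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	PTPRM	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	PVRL1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	SERPINE1	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	VCL	up
hsa-miR-34c-5p	hsa-miR-34c-5p	down	YY1	up
hsa-miR-429	hsa-miR-429	down	MIB1	up
hsa-miR-429	hsa-miR-429	down	MLL5	up
hsa-miR-429	hsa-miR-429	down	NDST1	up
hsa-miR-429	hsa-miR-429	down	RHOA	up
hsa-miR-429	hsa-miR-429	down	RND3	up
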