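tf	mirna	target_gene
ETS2	hsa-miR-199b-5p	ETS2
ETS2	hsa-miR-203	ETS2
ETS2	hsa-miR-222	ETS2
ETS2	hsa-miR-335	ETS2
ETS2	hsa-miR-429	ETS2
SP1	hsa-miR-1	SP1
SP1	hsa-miR-130a	SP1
SP1	hsa-miR-130b	SP1
SP1	hsa-miR-135a	SP1
SP1	hsa-miR-148b	SP1
SP1	hsa-miR-149	SP1
SP1	hsa-miR-181c	SP1
SP1	hsa-miR-199b-5p	SP1
SP1	hsa-miR-203	SP1
SP1	hsa-miR-206	SP1
SP1	hsa-miR-32	SP1
SP1	hsa-miR-335	SP1
SP1	hsa-miR-429	SP1
SP1	hsa-miR-486-3p	SP1
KLF6	hsa-miR-181c	KLF6
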