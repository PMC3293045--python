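stage	direction	mirna
I-II	down	hsa-miR-449a
I-II	down	hsa-miR-34c-3p
I-II	down	hsa-miR-32
I-II	down	hsa-miR-34b
I-II	down	hsa-miR-625
I-II	down	hsa-miR-34b*
I-II	down	hsa-miR-34c-5p
I-II	up	hsa-miR-455-5p
I-II	up	hsa-miR-199b-5p
I-II	up	hsa-miR-409-3p
I-II	up	hsa-miR-411
I-II	up	hsa-miR-107
III	down	hsa-miR-34b
III	down	hsa-miR-34c-3p
III	down	hsa-miR-34b*
III	down	hsa-miR-449a
III	down	hsa-miR-34c-5p
III	up	hsa-miR-17-5p:9.1
III	up	hsa-miR-107
III	up	hsa-miR-409-3p
III	up	hsa-miR-18a
III	up	hsa-miR-339-5p
III	up	hsa-miR-99a
III	up	hsa-miR-34a*
III	up	hsa-miR-411
III	up	hsa-miR-455-5p
III	up	hsa-miR-149
IV	down	hsa-miR-32
IV	down	hsa-miR-449a
IV	up	hsa-miR-99a
IV	up	hsa-miR-199b-5p
IV	up	hsa-miR-99b
IV	up	hsa-miR-339-5p
IV	up	hsa-miR-708
IV	up	hsa-miR-200a*
IV	up	hsa-miR-18b
IV	up	hsa-miR-20a*
IV	up	hsa-miR-409-3p
IV	up	hsa-miR-107
IV	up	hsa-miR-18a*
IV	up	hsa-miR-17-5p:9.1
IV	up	hsa-miR-34a*
IV	up	hsa-miR-503
IV	up	hsa-miR-455-5p
IV	up	hsa-miR-411
IV	up	hsa-miR-18a
IV	up	hsa-miR-149
MET	down	hsa-miR-449a
MET	down	hsa-miR-32
MET	down	hsa-miR-34b*
MET	down	hsa-miR-34c-5p
MET	down	hsa-miR-186
MET	down	hsa-miR-130b
MET	down	hsa-miR-34c-3p
MET	down	hsa-miR-34b
MET	down	hsa-miR-181c
MET	down	hsa-miR-361-3p
MET	down	hsa-miR-429
MET	down	hsa-miR-625
MET	down	hsa-miR-335
MET	down	hsa-let-7c
MET	down	hsa-miR-29c
MET	down	hsa-miR-421
MET	down	hsa-miR-141
MET	down	hsa-miR-29a
MET	up	hsa-miR-708
MET	up	hsa-miR-149
MET	up	hsa-miR-20a*
MET	up	hsa-miR-34a*
MET	up	hsa-miR-99a
MET	up	hsa-miR-107
MET	up	hsa-let-7d*
MET	up	hsa-miR-483-3p
MET	up	hsa-miR-18b
MET	up	hsa-miR-455-5p
MET	up	hsa-miR-199b-5p
MET	up	hsa-miR-193a-5p
MET	up	hsa-miR-99b
MET	up	hsa-miR-503
MET	up	hsa-miR-18a
MET	up	hsa-miR-409-3p
MET	up	hsa-miR-411
MET	up	hsa-miR-1
MET	up	hsa-miR-206
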