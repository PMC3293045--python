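stage	tf
I-II	ETS2
I-II	MYB
I-II	Sp1
I-II	KLF6
I-II	NFE2
I-II	PCBP1
I-II	TMEM54
III	ETS2
III	MYB
III	KLF6
III	Sp1
III	PCBP1
III	TMEM54
III	YY1
III	NFE2
IV	ETS2
IV	MYB
IV	NFE2
IV	PCBP1
IV	APP
IV	KLF6
IV	Sp1
IV	TMEM54
IV	YY1
IV	RUNX2
IV	TFCP2
IV	TEAD2
IV	NR3C1
IV	TFAP2A
MET	ETS2
MET	MYB
MET	NFE2
MET	Sp1
MET	YY1
MET	KLF6
MET	TMEM54
MET	ESR1
MET	PCBP1
MET	APP
MET	TEAD2
MET	RUNX2
MET	TFCP2
MET	TFAP2A
MET	MAZ
MET	NR3C1
MET	TBP
MET	WT1
MET	MYC
MET	AP1S1
MET	USF1
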