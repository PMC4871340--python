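ligand_id	name	gprotein_emax	barrestin_emax
BI	BI-167107	100	100
ISO	Isoprenaline	99.14	80.47
FEN	Fenoterol	102.2	70.17
FOR	Formoterol	104.6	99.75
SAM	Salmeterol	111.8	23.26
CLE	Clenbuterol	112.8	21.35
SAL	Salbutamol	107.3	32.41
NOR	Norepinephrine	107.4	24.89
DOB	Dobutamine	96.77	4.803
EPI	Epinephrine	93.52	62.84
DCI	Dichloroisoproterenol	43.35	2.626
PIN	Pindolol	15.48	1.979
CAU	Carazolol	0	0
ICI	ICI-118551	0	0
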