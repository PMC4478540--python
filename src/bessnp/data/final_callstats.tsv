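species	sample	missing_n	het_n
hirsutum	TM-1	2144	16880
hirsutum	Sealand 542	4180	22460
hirsutum	PD-1	4435	27039
hirsutum	Paymaster HS-26	4450	38201
hirsutum	M-240 RNR	4146	30450
hirsutum	Fibermax 832	4994	31862
hirsutum	Coker 312	4604	21831
hirsutum	SureGrow 747	4187	21589
hirsutum	Stoneville 474	4058	21554
hirsutum	Tamcot Sphinx	5934	22342
hirsutum	Acala Maxxa	5159	20207
hirsutum	TX0231	12057	24974
barbadense	3-79	43530	20443
longicalyx	F1-1	221786	30204
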