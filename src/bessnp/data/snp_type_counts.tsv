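tier	M	R	W	S	Y	K
hirsutum	11146	45444	11992	6862	45408	11410
barbadense	16558	64420	16021	9188	64574	16594
longicalyx	42802	139410	60070	25420	139620	43255
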