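tier	genic_n	nongenic_n
hirsutum	10329	121933
barbadense	13274	174081
longicalyx	97366	353211
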