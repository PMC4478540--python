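marker	section	kasp_result	identified_iter1	identified_iter2	removal_iter1	removal_iter2	final_iter1	final_iter2
GH_TBb001A07f_381	non-transcriptome	Good	Yes	Yes	Retain	Retain	Good	Good
GH_TBb001A07f_486	non-transcriptome	Bad	No	Yes	NA	Remove	NA	NA
GH_TBb001A23r_531	non-transcriptome	Bad	No	Yes	NA	Retain	NA	Bad
GH_TBb001A23r_614	non-transcriptome	Good	Yes	Yes	Retain	Retain	Good	Good
GH_TBb001D22r_204	non-transcriptome	Good	Yes	Yes	Retain	Retain	Good	Good
GH_TBb001D22r_445	non-transcriptome	Bad	Yes	No	Retain	NA	Bad	NA
GH_TBb001D22r_511	non-transcriptome	Bad	Yes	Yes	Retain	Retain	Bad	Bad
GH_TBb001B05f_180	non-transcriptome	Good	Yes	Yes	Remove	Remove	NA	NA
GH_TBb001B05f_564	non-transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBb001C03f_116	non-transcriptome	Good	No	Yes	NA	Retain	NA	Good
GH_TBb001C03f_401	non-transcriptome	Good	Yes	Yes	Retain	Retain	Good	Good
GH_TBb001F01r_117	non-transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBb001F01r_310	non-transcriptome	Bad	Yes	No	Remove	NA	NA	NA
GH_TBb001A17r_218	non-transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBb001F06f_303	non-transcriptome	Bad	No	Yes	NA	Remove	NA	NA
GH_TBb004J20r_76	transcriptome	Good	Yes	Yes	Remove	Remove	NA	NA
GH_TBb004J20r_348	transcriptome	Good	Yes	Yes	Retain	Retain	Good	Good
GH_TBb053N14f_270	transcriptome	Good	Yes	Yes	Retain	Retain	Good	Good
Gh_TBh036B20r_583	transcriptome	Good	No	Yes	NA	Retain	NA	Good
GH_TBr162H20f_547	transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBb046O02r_64	transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBb046O02r_138	transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBb046O02r_418	transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBb069A06f_248	transcriptome	Bad	Yes	No	Retain	NA	Bad	NA
GH_TBb069A06f_304	transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBh034D07r_276	transcriptome	Good	Yes	Yes	Retain	Retain	Good	Good
GH_TBh030P12r_332	transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBb119O19f_465	transcriptome	Maybe	Yes	Yes	Retain	Retain	NA	NA
GH_TBh055K17f_57	transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBh055K17f_506	transcriptome	Bad	Yes	Yes	Remove	Remove	NA	NA
GH_TBh023O21f_162	transcriptome	Good	Yes	Yes	Remove	Retain	NA	Good
GH_TBh023O21f_537	transcriptome	Good	Yes	Yes	Retain	Retain	Good	Good
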