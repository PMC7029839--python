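subject_id	group	age	sex	vas_pain	stm_index
CN_013	CN	61	F	NA	0.1125
CN_017	CN	65	F	NA	0.2861
CN_034	CN	58	M	NA	0.302
CN_035	CN	53	F	NA	0.3628
CN_036	CN	47	M	NA	0.3322
CN_038	CN	51	F	NA	0.1955
CN_039	CN	61	F	NA	0.2392
CN_040	CN	64	F	NA	0.3009
CN_041	CN	46	M	NA	0.3367
CN_042	CN	65	F	NA	0.0626
CN_045	CN	49	F	NA	0.4964
CN_046	CN	53	F	NA	0.2933
CN_048	CN	63	F	NA	0.118
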