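subject_id	group	age	sex	vas_pain	stm_index
FBSS_01	FBSS	51	F	7	0.118
FBSS_02	FBSS	47	F	4.5	0.137
FBSS_03	FBSS	68	M	7.5	0.073
FBSS_04	FBSS	68	M	5	0.135
FBSS_05	FBSS	40	F	9	0.019
FBSS_06	FBSS	45	F	7	0.042
FBSS_07	FBSS	50	M	5	NA
FBSS_08	FBSS	60	F	8	0.060
FBSS_09	FBSS	33	M	5	0.184
FBSS_10	FBSS	61	M	6	0.141
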