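variant	SAS_NADP	SAS_NADP_sd	SAS_hPGS	SAS_hPGS_sd	IE_P_hP	IE_P_hP_sd	IE_N_hP	IE_N_hP_sd
WT	1.10	0.26	0.98	0.43	-122.91	23.60	-9.75	7.74
L213Q	1.55	0.35	1.46	0.59	-105.66	23.88	-5.22	6.17
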