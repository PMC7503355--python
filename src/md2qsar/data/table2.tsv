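variant	IE_P_hP	IE_P_hP_sd	IE_N_hP	IE_N_hP_sd	Km	Km_sd	kcat	kcat_over_Km	measured
R304L	-119.28	81.07	-31.77	8.89	283.3	13.2	96.1	0.3	True
E127D	-97.50	63.49	-14.29	9.22	9.4	2.5	4.4	0.4	True
H222I	-111.04	67.84	-28.61	8.76	28.6	5.2	18.5	0.6	True
H222S	-110.99	68.25	-8.57	5.19	25.6	5.7	39.6	1.5	True
L213Q	-114.93	24.89	-8.90	6.87	5.1		38.2	7.55	False
T307V	-126.19	70.32	-33.38	7.61	4.1	0.3	41.3	10	True
WT	-118.72	13.23	-5.69	7.10	4.2	0.8	65.1	15.2	True
D309L	-126.98	83.16	-19.78	10.08	4.6	0.6	119.5	25.9	True
Y305F	-120.12	84.75	-19.72	6.08	5.6	1.9	156.3	27.9	True
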