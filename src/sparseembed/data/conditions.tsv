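feature	axis	level	pole_a	La	Ma	Sa	pole_b	Lb	Mb	Sb
LM_high_sat	LM	95	DKL0_95	5.730	-10.198	0.066	DKL180_95	-5.361	11.012	0.303
LM_med_sat	LM	50	DKL0_50	3.523	-4.981	0.253	DKL180_50	-2.627	5.839	0.347
LM_low_sat	LM	30	DKL0_30	2.189	-3.165	0.314	DKL180_30	-1.436	3.799	-0.047
LM_xlow_sat	LM	10	DKL0_10	0.674	-1.177	0.239	DKL180_10	-0.720	1.056	-0.705
S_high_sat	S	95	DKL90_95	-0.078	-0.817	-59.771	DKL270_95	-0.398	-0.408	60.353
S_med_sat	S	50	DKL90_50	0.353	0.268	-32.172	DKL270_50	-0.361	-0.426	31.988
S_low_sat	S	30	DKL90_30	0.233	0.220	-19.798	DKL270_30	-0.036	-0.125	19.624
S_xlow_sat	S	10	DKL90_10	-0.264	-0.419	-6.746	DKL270_10	-0.058	-0.033	6.443
Daylight_high_sat	daylight	95	DKL45_95	4.356	-7.987	-40.341	DKL225_95	-4.073	7.226	42.951
Daylight_med_sat	daylight	50	DKL45_50	2.431	-3.558	-22.835	DKL225_50	-2.322	3.686	22.322
Daylight_low_sat	daylight	30	DKL45_30	1.615	-2.080	-13.190	DKL225_30	-1.529	2.087	13.540
Daylight_xlow_sat	daylight	10	DKL45_10	0.733	-0.514	-3.895	DKL225_10	-0.341	0.848	3.940
Antidaylight_high_sat	antidaylight	95	DKL135_95	-3.898	7.641	-43.922	DKL315_95	3.745	-7.725	42.740
Antidaylight_med_sat	antidaylight	50	DKL135_50	-1.725	4.252	-22.838	DKL315_50	1.830	-4.139	22.837
Antidaylight_low_sat	antidaylight	30	DKL135_30	-1.253	2.212	-14.045	DKL315_30	1.197	-2.642	13.868
Antidaylight_xlow_sat	antidaylight	10	DKL135_10	-0.309	0.970	-4.477	DKL315_10	0.592	-0.739	4.771
LMS_high_sat	LMS	95	Light_95	8.400	8.325	5.795	Dark_95	-8.989	-8.901	-6.309
LMS_med_sat	LMS	50	Light_50	5.678	5.638	4.008	Dark_50	-5.298	-5.223	-3.808
LMS_low_sat	LMS	30	Light_30	2.520	2.516	1.741	Dark_30	-2.526	-2.510	-1.757
LMS_xlow_sat	LMS	10	Light_10	1.219	1.283	0.889	Dark_10	-1.071	-1.072	-0.932
LM_high_freq	LM	8	LM_8cpd	6.957	12.923	0.400	LM_8cpd	6.957	12.923	0.400
LM_med_freq	LM	4	LM_4cpd	6.957	12.923	0.400	LM_4cpd	6.957	12.923	0.400
LM_low_freq	LM	0.2	LM_0.2cpd	6.957	12.923	0.400	LM_0.2cpd	6.957	12.923	0.400
S_high_freq	S	8	S_8cpd	0.110	0.250	71.845	S_8cpd	0.110	0.250	71.845
S_med_freq	S	4	S_4cpd	0.110	0.250	71.845	S_4cpd	0.110	0.250	71.845
S_low_freq	S	0.2	S_0.2cpd	0.110	0.250	71.845	S_0.2cpd	0.110	0.250	71.845
LMS_high_freq	LMS	8	LMS_8cpd	7.137	7.067	6.487	LMS_8cpd	7.137	7.067	6.487
LMS_med_freq	LMS	4	LMS_4cpd	7.137	7.067	6.487	LMS_4cpd	7.137	7.067	6.487
LMS_low_freq	LMS	0.2	LMS_0.2cpd	7.137	7.067	6.487	LMS_0.2cpd	7.137	7.067	6.487
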