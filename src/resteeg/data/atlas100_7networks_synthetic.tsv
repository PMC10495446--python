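roi_index	roi_name	network	x	y	z
0	LH_SalienceVentralAttention_1	SalienceVentralAttention	-0.002747	0.007066	0.069588
1	RH_SalienceVentralAttention_2	SalienceVentralAttention	0.011741	-0.005793	0.068765
2	LH_SalienceVentralAttention_3	SalienceVentralAttention	-0.016181	-0.004710	0.067941
3	RH_Limbic_1	Limbic	0.010321	0.016991	0.067118
4	RH_DorsalAttention_1	DorsalAttention	0.004371	-0.022045	0.066294
5	LH_Limbic_2	Limbic	-0.019966	0.014662	0.065471
6	RH_SalienceVentralAttention_4	SalienceVentralAttention	0.026690	0.002899	0.064647
7	LH_DorsalAttention_2	DorsalAttention	-0.018978	-0.021596	0.063824
8	LH_Limbic_3	Limbic	-0.000630	0.030506	0.063000
9	RH_DorsalAttention_3	DorsalAttention	0.022207	-0.023258	0.062176
10	LH_SalienceVentralAttention_5	SalienceVentralAttention	-0.033627	0.002252	0.061353
11	RH_Limbic_4	Limbic	0.027455	0.021964	0.060529
12	LH_SomatoMotor_1	SomatoMotor	-0.005620	-0.036106	0.059706
13	LH_Control_1	Control	-0.020973	0.031512	0.058882
14	RH_DorsalAttention_4	DorsalAttention	0.037966	-0.009369	0.058059
15	LH_DorsalAttention_5	DorsalAttention	-0.035373	-0.019310	0.057235
16	RH_Control_2	Control	0.013410	0.039216	0.056412
17	RH_SomatoMotor_2	SomatoMotor	0.017042	-0.038981	0.055588
18	LH_Limbic_5	Limbic	-0.039862	0.017659	0.054765
19	RH_Limbic_6	Limbic	0.042283	0.014229	0.053941
20	LH_SomatoMotor_3	SomatoMotor	-0.022040	-0.039910	0.053118
21	LH_Control_3	Control	-0.010929	0.045232	0.052294
22	RH_DorsalAttention_6	DorsalAttention	0.039366	-0.026478	0.051471
23	LH_SalienceVentralAttention_6	SalienceVentralAttention	-0.047781	-0.007199	0.050647
24	RH_Control_4	Control	0.030903	0.038244	0.049824
25	RH_SomatoMotor_4	SomatoMotor	0.003097	-0.049894	0.049000
26	LH_Control_5	Control	-0.036558	0.035249	0.048176
27	RH_SalienceVentralAttention_7	SalienceVentralAttention	0.051536	-0.001317	0.047353
28	LH_SomatoMotor_5	SomatoMotor	-0.039452	-0.034330	0.046529
29	RH_Default_1	Default	0.005983	0.052680	0.045706
30	RH_SomatoMotor_6	SomatoMotor	0.031584	-0.043451	0.044882
31	LH_Limbic_7	Limbic	-0.053304	0.010840	0.044059
32	RH_Limbic_8	Limbic	0.047190	0.028352	0.043235
33	LH_Visual_1	Visual	-0.015826	-0.053393	0.042412
34	LH_Control_6	Control	-0.024667	0.050616	0.041588
35	RH_DorsalAttention_7	DorsalAttention	0.052937	-0.020880	0.040765
36	LH_DorsalAttention_8	DorsalAttention	-0.053680	-0.020570	0.039941
37	RH_Default_2	Default	0.025939	0.051932	0.039118
38	RH_Visual_2	Visual	0.016103	-0.056340	0.038294
39	LH_Limbic_9	Limbic	-0.050383	0.030943	0.037471
40	RH_Limbic_10	Limbic	0.058558	0.011314	0.036647
41	LH_SomatoMotor_7	SomatoMotor	-0.035833	-0.048298	0.035824
42	LH_Default_3	Default	-0.006253	0.060298	0.035000
43	RH_SomatoMotor_8	SomatoMotor	0.045692	-0.040549	0.034176
44	LH_SalienceVentralAttention_8	SalienceVentralAttention	-0.061536	-0.000972	0.033353
45	RH_Control_7	Control	0.045037	0.042585	0.032529
46	LH_Visual_3	Visual	-0.004474	-0.062247	0.031706
47	LH_Control_8	Control	-0.039004	0.049244	0.030882
48	RH_DorsalAttention_9	DorsalAttention	0.062417	-0.010027	0.030059
49	LH_SomatoMotor_9	SomatoMotor	-0.053120	-0.034980	0.029235
50	RH_Default_4	Default	0.015631	0.062036	0.028412
51	RH_Visual_4	Visual	0.030550	-0.056618	0.027588
52	LH_Limbic_11	Limbic	-0.061099	0.021226	0.026765
53	RH_Limbic_12	Limbic	0.059698	0.025753	0.025941
54	LH_Visual_5	Visual	-0.026756	-0.059609	0.025118
55	LH_Default_5	Default	-0.020634	0.062322	0.024294
56	RH_SomatoMotor_10	SomatoMotor	0.057574	-0.032162	0.023471
57	LH_DorsalAttention_10	DorsalAttention	-0.064458	-0.015241	0.022647
58	RH_Default_6	Default	0.037389	0.055007	0.021824
59	RH_Visual_6	Visual	0.009626	-0.066078	0.021000
60	LH_Control_9	Control	-0.051929	0.042382	0.020176
61	RH_SalienceVentralAttention_9	SalienceVentralAttention	0.067162	0.003840	0.019353
62	LH_SomatoMotor_11	SomatoMotor	-0.047091	-0.048365	0.018529
63	RH_Default_7	Default	0.002060	0.067692	0.017706
64	RH_Visual_7	Visual	0.044344	-0.051465	0.016882
65	LH_SalienceVentralAttention_10	SalienceVentralAttention	-0.067660	0.008018	0.016059
66	RH_Control_10	Control	0.055460	0.039901	0.015235
67	LH_Visual_8	Visual	-0.013978	-0.067059	0.014412
68	LH_Default_8	Default	-0.035077	0.059034	0.013588
69	RH_DorsalAttention_11	DorsalAttention	0.065892	-0.019881	0.012765
70	LH_DorsalAttention_12	DorsalAttention	-0.062149	-0.029914	0.011941
71	RH_Default_9	Default	0.025672	0.064167	0.011118
72	RH_Visual_9	Visual	0.024460	-0.064775	0.010294
73	LH_Control_11	Control	-0.061895	0.031294	0.009471
74	RH_Limbic_13	Limbic	0.066882	0.018764	0.008647
75	LH_Visual_10	Visual	-0.036693	-0.059097	0.007824
76	LH_Default_10	Default	-0.012879	0.068448	0.007000
77	RH_SomatoMotor_12	SomatoMotor	0.055795	-0.041818	0.006176
78	LH_SalienceVentralAttention_11	SalienceVentralAttention	-0.069457	-0.006860	0.005353
79	RH_Default_11	Default	0.046621	0.052019	0.004529
80	RH_Visual_11	Visual	0.000762	-0.069898	0.003706
81	LH_Control_12	Control	-0.047804	0.051054	0.002882
82	RH_SalienceVentralAttention_12	SalienceVentralAttention	0.069764	-0.005356	0.002059
83	LH_SomatoMotor_13	SomatoMotor	-0.055076	-0.043187	0.001235
84	RH_Default_12	Default	0.011440	0.069058	0.000412
85	RH_Visual_12	Visual	0.038212	-0.058649	-0.000412
86	LH_Limbic_14	Limbic	-0.067784	0.017431	-0.001235
87	RH_Control_13	Control	0.061739	0.032925	-0.002059
88	LH_Visual_13	Visual	-0.023274	-0.065955	-0.002882
89	LH_Default_13	Default	-0.027375	0.064319	-0.003706
90	RH_DorsalAttention_13	DorsalAttention	0.063588	-0.028915	-0.004529
91	LH_DorsalAttention_14	DorsalAttention	-0.066364	-0.021614	-0.005353
92	RH_Default_14	Default	0.034301	0.060706	-0.006176
93	RH_Visual_14	Visual	0.015696	-0.067857	-0.007000
94	LH_Control_14	Control	-0.057339	0.039384	-0.007824
95	RH_SalienceVentralAttention_13	SalienceVentralAttention	0.068786	0.009678	-0.008647
96	LH_Visual_15	Visual	-0.044115	-0.053518	-0.009471
97	LH_Default_15	Default	-0.003615	0.069144	-0.010294
98	RH_SomatoMotor_14	SomatoMotor	0.049281	-0.048454	-0.011118
99	LH_SalienceVentralAttention_14	SalienceVentralAttention	-0.068931	0.002434	-0.011941
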