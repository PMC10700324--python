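index	name	abbreviation	hemisphere	network
1	Precentral_L	PreCG.L	left	SMC
2	Precentral_R	PreCG.R	right	SMC
3	Frontal_Sup_L	SFGdor.L	left	EAN
4	Frontal_Sup_R	SFGdor.R	right	EAN
5	Frontal_Sup_Orb_L	ORBsup.L	left	DMN
6	Frontal_Sup_Orb_R	ORBsup.R	right	DMN
7	Frontal_Mid_L	MFG.L	left	EAN
8	Frontal_Mid_R	MFG.R	right	EAN
9	Frontal_Mid_Orb_L	ORBmid.L	left	DMN
10	Frontal_Mid_Orb_R	ORBmid.R	right	DMN
11	Frontal_Inf_Oper_L	IFGoperc.L	left	EAN
12	Frontal_Inf_Oper_R	IFGoperc.R	right	EAN
13	Frontal_Inf_Tri_L	IFGtriang.L	left	EAN
14	Frontal_Inf_Tri_R	IFGtriang.R	right	EAN
15	Frontal_Inf_Orb_L	ORBinf.L	left	DMN
16	Frontal_Inf_Orb_R	ORBinf.R	right	DMN
17	Rolandic_Oper_L	ROL.L	left	SMC
18	Rolandic_Oper_R	ROL.R	right	SMC
19	Supp_Motor_Area_L	SMA.L	left	SMC
20	Supp_Motor_Area_R	SMA.R	right	SMC
21	Olfactory_L	OLF.L	left	SN
22	Olfactory_R	OLF.R	right	SN
23	Frontal_Sup_Medial_L	SFGmed.L	left	EAN
24	Frontal_Sup_Medial_R	SFGmed.R	right	EAN
25	Frontal_Med_Orb_L	ORBsupmed.L	left	DMN
26	Frontal_Med_Orb_R	ORBsupmed.R	right	DMN
27	Rectus_L	REC.L	left	DMN
28	Rectus_R	REC.R	right	DMN
29	Insula_L	INS.L	left	EAN
30	Insula_R	INS.R	right	EAN
31	Cingulum_Ant_L	ACG.L	left	DMN
32	Cingulum_Ant_R	ACG.R	right	DMN
33	Cingulum_Mid_L	DCG.L	left	EAN
34	Cingulum_Mid_R	DCG.R	right	EAN
35	Cingulum_Post_L	PCG.L	left	DMN
36	Cingulum_Post_R	PCG.R	right	DMN
37	Hippocampus_L	HIP.L	left	SN
38	Hippocampus_R	HIP.R	right	SN
39	ParaHippocampal_L	PHG.L	left	SN
40	ParaHippocampal_R	PHG.R	right	SN
41	Amygdala_L	AMYG.L	left	SN
42	Amygdala_R	AMYG.R	right	SN
43	Calcarine_L	CAL.L	left	VC
44	Calcarine_R	CAL.R	right	VC
45	Cuneus_L	CUN.L	left	VC
46	Cuneus_R	CUN.R	right	VC
47	Lingual_L	LING.L	left	VC
48	Lingual_R	LING.R	right	VC
49	Occipital_Sup_L	SOG.L	left	VC
50	Occipital_Sup_R	SOG.R	right	VC
51	Occipital_Mid_L	MOG.L	left	VC
52	Occipital_Mid_R	MOG.R	right	VC
53	Occipital_Inf_L	IOG.L	left	VC
54	Occipital_Inf_R	IOG.R	right	VC
55	Fusiform_L	FFG.L	left	VC
56	Fusiform_R	FFG.R	right	VC
57	Postcentral_L	PoCG.L	left	SMC
58	Postcentral_R	PoCG.R	right	SMC
59	Parietal_Sup_L	SPG.L	left	SMC
60	Parietal_Sup_R	SPG.R	right	SMC
61	Parietal_Inf_L	IPL.L	left	EAN
62	Parietal_Inf_R	IPL.R	right	EAN
63	SupraMarginal_L	SMG.L	left	EAN
64	SupraMarginal_R	SMG.R	right	EAN
65	Angular_L	ANG.L	left	DMN
66	Angular_R	ANG.R	right	DMN
67	Precuneus_L	PCUN.L	left	DMN
68	Precuneus_R	PCUN.R	right	DMN
69	Paracentral_Lobule_L	PCL.L	left	SMC
70	Paracentral_Lobule_R	PCL.R	right	SMC
71	Caudate_L	CAU.L	left	SN
72	Caudate_R	CAU.R	right	SN
73	Putamen_L	PUT.L	left	SN
74	Putamen_R	PUT.R	right	SN
75	Pallidum_L	PAL.L	left	SN
76	Pallidum_R	PAL.R	right	SN
77	Thalamus_L	THA.L	left	SN
78	Thalamus_R	THA.R	right	SN
79	Heschl_L	HES.L	left	SMC
80	Heschl_R	HES.R	right	SMC
81	Temporal_Sup_L	STG.L	left	SMC
82	Temporal_Sup_R	STG.R	right	SMC
83	Temporal_Pole_Sup_L	TPOsup.L	left	EAN
84	Temporal_Pole_Sup_R	TPOsup.R	right	EAN
85	Temporal_Mid_L	MTG.L	left	DMN
86	Temporal_Mid_R	MTG.R	right	DMN
87	Temporal_Pole_Mid_L	TPOmid.L	left	SN
88	Temporal_Pole_Mid_R	TPOmid.R	right	SN
89	Temporal_Inf_L	ITG.L	left	DMN
90	Temporal_Inf_R	ITG.R	right	DMN
91	Cerebelum_Crus1_L	CRBLCrus1.L	left	Cereb
92	Cerebelum_Crus1_R	CRBLCrus1.R	right	Cereb
93	Cerebelum_Crus2_L	CRBLCrus2.L	left	Cereb
94	Cerebelum_Crus2_R	CRBLCrus2.R	right	Cereb
95	Cerebelum_3_L	CRBL3.L	left	Cereb
96	Cerebelum_3_R	CRBL3.R	right	Cereb
97	Cerebelum_4_5_L	CRBL45.L	left	Cereb
98	Cerebelum_4_5_R	CRBL45.R	right	Cereb
99	Cerebelum_6_L	CRBL6.L	left	Cereb
100	Cerebelum_6_R	CRBL6.R	right	Cereb
101	Cerebelum_7b_L	CRBL7b.L	left	Cereb
102	Cerebelum_7b_R	CRBL7b.R	right	Cereb
103	Cerebelum_8_L	CRBL8.L	left	Cereb
104	Cerebelum_8_R	CRBL8.R	right	Cereb
105	Cerebelum_9_L	CRBL9.L	left	Cereb
106	Cerebelum_9_R	CRBL9.R	right	Cereb
107	Cerebelum_10_L	CRBL10.L	left	Cereb
108	Cerebelum_10_R	CRBL10.R	right	Cereb
109	Vermis_1_2	Vermis12	midline	Cereb
110	Vermis_3	Vermis3	midline	Cereb
111	Vermis_4_5	Vermis45	midline	Cereb
112	Vermis_6	Vermis6	midline	Cereb
113	Vermis_7	Vermis7	midline	Cereb
114	Vermis_8	Vermis8	midline	Cereb
115	Vermis_9	Vermis9	midline	Cereb
116	Vermis_10	Vermis10	midline	Cereb
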