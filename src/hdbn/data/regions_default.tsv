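id	abbreviation	name	hemisphere
0	LCC	corpus callosum, left	L
1	LCB	cerebellum, left	L
2	LSUC	superior colliculus, motor related, left	L
3	LHY	hypothalamus, left	L
4	LIC	inferior colliculus, left	L
5	LCOA	cortical amygdalar area, left	L
6	LMO	somatomotor areas, left	L
7	LSS	somatosensory areas, left	L
8	LPIR	piriform area, left	L
9	LTT	taenia tecta, left	L
10	LRHP	retrohippocampal region, left	L
11	LMB	midbrain, left	L
12	LCA1	hippocampal field CA1, left	L
13	LCA2	hippocampal field CA2, left	L
14	LCA3	hippocampal field CA3, left	L
15	LDG	dentate gyrus, left	L
16	LEC	entorhinal cortex, left	L
17	LTH	thalamus, left	L
18	LICtx	isocortex, left	L
19	LMED	medulla, left	L
20	LPONS	pons, left	L
21	LPL01	placeholder region 01 (override via custom table), left	L
22	LPL02	placeholder region 02 (override via custom table), left	L
23	LPL03	placeholder region 03 (override via custom table), left	L
24	LPL04	placeholder region 04 (override via custom table), left	L
25	LPL05	placeholder region 05 (override via custom table), left	L
26	LPL06	placeholder region 06 (override via custom table), left	L
27	LPL07	placeholder region 07 (override via custom table), left	L
28	LPL08	placeholder region 08 (override via custom table), left	L
29	LPL09	placeholder region 09 (override via custom table), left	L
30	LPL10	placeholder region 10 (override via custom table), left	L
31	LPL11	placeholder region 11 (override via custom table), left	L
32	LPL12	placeholder region 12 (override via custom table), left	L
33	LPL13	placeholder region 13 (override via custom table), left	L
34	LPL14	placeholder region 14 (override via custom table), left	L
35	LPL15	placeholder region 15 (override via custom table), left	L
36	RCC	corpus callosum, right	R
37	RCB	cerebellum, right	R
38	RSUC	superior colliculus, motor related, right	R
39	RHY	hypothalamus, right	R
40	RIC	inferior colliculus, right	R
41	RCOA	cortical amygdalar area, right	R
42	RMO	somatomotor areas, right	R
43	RSS	somatosensory areas, right	R
44	RPIR	piriform area, right	R
45	RTT	taenia tecta, right	R
46	RRHP	retrohippocampal region, right	R
47	RMB	midbrain, right	R
48	RCA1	hippocampal field CA1, right	R
49	RCA2	hippocampal field CA2, right	R
50	RCA3	hippocampal field CA3, right	R
51	RDG	dentate gyrus, right	R
52	REC	entorhinal cortex, right	R
53	RTH	thalamus, right	R
54	RICtx	isocortex, right	R
55	RMED	medulla, right	R
56	RPONS	pons, right	R
57	RPL01	placeholder region 01 (override via custom table), right	R
58	RPL02	placeholder region 02 (override via custom table), right	R
59	RPL03	placeholder region 03 (override via custom table), right	R
60	RPL04	placeholder region 04 (override via custom table), right	R
61	RPL05	placeholder region 05 (override via custom table), right	R
62	RPL06	placeholder region 06 (override via custom table), right	R
63	RPL07	placeholder region 07 (override via custom table), right	R
64	RPL08	placeholder region 08 (override via custom table), right	R
65	RPL09	placeholder region 09 (override via custom table), right	R
66	RPL10	placeholder region 10 (override via custom table), right	R
67	RPL11	placeholder region 11 (override via custom table), right	R
68	RPL12	placeholder region 12 (override via custom table), right	R
69	RPL13	placeholder region 13 (override via custom table), right	R
70	RPL14	placeholder region 14 (override via custom table), right	R
71	RPL15	placeholder region 15 (override via custom table), right	R
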