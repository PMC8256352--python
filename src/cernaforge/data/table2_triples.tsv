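id	mrna	mirna	lncrna
1	ADAMTS14	hsa-miR-4667-5p	LINC00662
2	ARGFX	hsa-miR-378f	DIRC3
3	ARGFX	hsa-miR-378f	LINC00662
4	ARGFX	hsa-miR-378f	LINC01133
5	ARGFX	hsa-miR-378f	RMST
6	BCAS1	hsa-miR-3650	LINC00662
7	BCAS1	hsa-miR-3650	LINC01119
8	CARNS1	hsa-miR-3650	LINC00662
9	CARNS1	hsa-miR-3650	LINC01119
10	CCBE1	hsa-miR-5009-3p	LINC00662
11	CCBE1	hsa-miR-5009-3p	SNHG3
12	CDCA3	hsa-miR-4668-5p	LINC00326
13	CDCA3	hsa-miR-4668-5p	LINC00662
14	CDCA3	hsa-miR-4668-5p	LINC00920
15	CDCA3	hsa-miR-4668-5p	LINC01119
16	CYP2W1	hsa-miR-6856-5p	LINC00662
17	CYP2W1	hsa-miR-6856-5p	LINC01133
18	FAM103A1	hsa-miR-4700-3p	LINC00326
19	FAM103A1	hsa-miR-4700-3p	LINC00662
20	FAM103A1	hsa-miR-4700-3p	LINC01119
21	FAM103A1	hsa-miR-4799-5p	LINC00460
22	FAM103A1	hsa-miR-4799-5p	LINC00944
23	FAM103A1	hsa-miR-4799-5p	PWAR6
24	FAM103A1	hsa-miR-4799-5p	ZNF582-AS1
25	FAM120AOS	hsa-miR-4775	DIRC3
26	FAM120AOS	hsa-miR-4775	GAS5
27	FAM120AOS	hsa-miR-4775	LINC00662
28	FAM120AOS	hsa-miR-4775	LINC00920
29	FAM120AOS	hsa-miR-4775	LINC01419
30	FAM120AOS	hsa-miR-4775	PWAR6
31	FAM120AOS	hsa-miR-4775	RMST
32	GJB1	hsa-miR-4436b-3p	GAS5
33	HOXB3	hsa-miR-4495	LINC00662
34	HOXB3	hsa-miR-4653-5p	LINC00460
35	HOXB3	hsa-miR-4653-5p	LINC01029
36	HOXB3	hsa-miR-504-5p	GAS5
37	LRAT	hsa-miR-3680-5p	RMST
38	MAG	hsa-miR-6856-5p	LINC00662
39	MAG	hsa-miR-6856-5p	LINC01133
40	MCOLN3	hsa-miR-4668-5p	LINC00326
41	MCOLN3	hsa-miR-4668-5p	LINC00662
42	MCOLN3	hsa-miR-4668-5p	LINC00920
43	MCOLN3	hsa-miR-4668-5p	LINC01119
44	MOG	hsa-miR-6736-3p	LINC01119
45	MOG	hsa-miR-6736-3p	RMST
46	MORC1	hsa-miR-3973	PWAR6
47	MORC1	hsa-miR-3973	ZNF582-AS1
48	MYRF	hsa-miR-378f	DIRC3
49	MYRF	hsa-miR-378f	LINC00662
50	MYRF	hsa-miR-378f	LINC01133
51	MYRF	hsa-miR-378f	RMST
52	PLP1	hsa-miR-6844	DIRC3
53	PLP1	hsa-miR-6844	LINC00460
54	PLP1	hsa-miR-6844	LINC00662
55	PLP1	hsa-miR-6844	LINC00920
56	PLP1	hsa-miR-6844	LINC01133
57	PLP1	hsa-miR-6844	PWAR6
58	PLP1	hsa-miR-6844	RMST
59	PLP1	hsa-miR-6844	ZNF582-AS1
60	PRLR	hsa-miR-548a-3p	LINC00326
61	PRLR	hsa-miR-548a-3p	LINC00662
62	PRLR	hsa-miR-548a-3p	LINC00944
63	PRLR	hsa-miR-548a-3p	PWAR6
64	PRLR	hsa-miR-548a-3p	SNHG3
65	RASGRP3	hsa-miR-6783-5p	LINC00662
66	RASGRP3	hsa-miR-6783-5p	LINC01419
67	SH3TC2	hsa-miR-4495	LINC00662
68	SH3TC2	hsa-miR-4653-5p	LINC00460
69	SH3TC2	hsa-miR-4653-5p	LINC01029
70	SH3TC2	hsa-miR-4780	LINC00662
71	SLC26A9	hsa-miR-4764-3p	LINC00662
72	SLC26A9	hsa-miR-4764-3p	RMST
73	SLC26A9	hsa-miR-6856-5p	LINC00662
74	SLC26A9	hsa-miR-6856-5p	LINC01133
75	SYNPO2L	hsa-miR-4678	RMST
76	SYNPO2L	hsa-miR-5589-5p	LINC00460
77	SYNPO2L	hsa-miR-5589-5p	LINC00662
78	SYNPO2L	hsa-miR-5589-5p	LINC00944
79	SYNPO2L	hsa-miR-5589-5p	LINC01029
80	SYNPO2L	hsa-miR-5589-5p	LINC01119
81	SYNPO2L	hsa-miR-5589-5p	RMST
82	SYNPO2L	hsa-miR-6736-3p	LINC01119
83	SYNPO2L	hsa-miR-6736-3p	RMST
84	TNFSF14	hsa-miR-3650	LINC00662
85	TNFSF14	hsa-miR-3650	LINC01119
86	TNFSF14	hsa-miR-4775	DIRC3
87	TNFSF14	hsa-miR-4775	GAS5
88	TNFSF14	hsa-miR-4775	LINC00662
89	TNFSF14	hsa-miR-4775	LINC00920
90	TNFSF14	hsa-miR-4775	LINC01419
91	TNFSF14	hsa-miR-4775	PWAR6
92	TNFSF14	hsa-miR-4775	RMST
93	TRAPPC3L	hsa-miR-4483	LINC00662
94	TUBAL3	hsa-miR-6783-5p	LINC00662
95	TUBAL3	hsa-miR-6783-5p	LINC01419
96	VSIG2	hsa-miR-569	GAS5
97	VSIG2	hsa-miR-569	LINC01133
98	VSIG2	hsa-miR-569	PWAR6
99	VSIG2	hsa-miR-569	RMST
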