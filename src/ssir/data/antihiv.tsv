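id	code	label	subset
1	FABFBIDLJ	+1	TRN
2	FABFBIDEN	+1	TRN
3	FABFBIDLN	-1	TRN
4	FABFBIDLB	-1	TRN
5	FABFBIDAN	-1	Ex1
6	FABFBIDBN	-1	TRN
7	FABFBIDCN	-1	TRN
8	FABFBIDDN	-1	TRN
9	FABLBIDLN	+1	TRN
10	FABLBIDLJ	+1	TRN
11	FABRBIDLJ	-1	TRN
12	FABLBIDLB	-1	Ex1
13	FABLBIDLL	+1	TRN
14	FABLBIDEN	+1	Ex1
15	FABLBIDEJ	+1	TRN
16	FABLBIDHJ	-1	TRN
17	FABLBIDMJ	-1	Ex1
18	FABNBIDLJ	+1	Ex1
19	FABKAIDLN	+1	TRN
20	FABKAIDLJ	+1	TRN
21	FABKAIDNJ	+1	TRN
22	FABKAIDLL	+1	TRN
23	FABKAIDLA	+1	TRN
24	FABKAIDLO	+1	TRN
25	FACKAIDEJ	+1	TRN
26	FACFBIDLJ	-1	TRN
27	FABFBIDEJ	-1	Ex1
28	FABKAIDLB	-1	TRN
29	FABKAIDLM	-1	TRN
30	FABKAIDMN	-1	TRN
31	FABKAIDKN	-1	TRN
32	FABMBIDHJ	-1	Ex1
33	FABGBIDLJ	-1	Ex1
34	FABGBIDLN	-1	Ex1
35	HABHBIDLK	-1	Ex1
36	FABFBIDLL	-1	Ex1
37	FADIBIDLJ	-1	Ex1
38	FADJBIDLJ	-1	TRN
39	FABMBIDMJ	-1	TRN
40	CBEFBJDEN	-1	TRN
41	CBEFBKDEN	-1	Ex1
42	CABTACDLJ	-1	TRN
43	CABTACDLN	-1	TRN
44	FABLAICLJ	-1	TRN
45	FABLBIALJ	-1	TRN
46	FABLBIBLJ	-1	Ex1
47	FABLAIALJ	-1	TRN
48	FABLAIBLJ	-1	Ex1
49	FABCBIDLJ	+1	TRN
50	FABABIDLJ	-1	TRN
51	FABBBIDLJ	+1	TRN
52	FAAEBIDLJ	+1	Ex1
53	FAAEBIDEN	+1	TRN
54	FAAEBIDEL	-1	TRN
55	FAADBIDLJ	-1	TRN
56	FAAEBIDLN	-1	Ex1
57	FAAEBIDLL	-1	Ex1
58	FABVBIDEN	+1	TRN
59	FABVBIDIN	-1	Ex1
60	FABVBIDON	-1	TRN
61	FABTAIDEJ	-1	TRN
62	FABTAIDEN	-1	TRN
63	FABTAIDLN	-1	TRN
64	FABTAIDLM	-1	Ex1
65	FABTAIDLL	-1	TRN
66	FABTAIDLA	-1	TRN
67	FABTAIDLO	-1	Ex1
68	FABTAIDLB	-1	TRN
69	FABTAIDLC	-1	TRN
70	FABTAIDEM	-1	Ex1
71	FABTAIDEA	-1	Ex1
72	FABTAIDEO	-1	Ex1
73	HABTAIDLJ	-1	Ex1
74	HABTAIDLN	-1	Ex1
75	FABVBIDJN	-1	TRN
76	FABVBIDAN	-1	TRN
77	FABVBIDHN	-1	TRN
78	FABVBIDGN	-1	TRN
79	FABVBIDFN	-1	TRN
80	FABVBIDEM	+1	Ex1
81	HABTAIDEM	+1	TRN
82	FABPAGDEN	+1	Ex1
83	FABPAEDLJ	+1	Ex1
84	FABPAEDEN	+1	Ex1
85	FABPAFDEN	+1	Ex1
86	FABPAHDEN	+1	Ex1
87	FABPADDEN	+1	Ex1
88	FABPAADEN	+1	TRN
89	CCBFAIDLN	-1	Ex1
90	CCBFAIDLJ	-1	Ex1
91	CCBFAIDEN	-1	Ex1
92	GBBPAIDLN	-1	Ex1
93	GBBPAIDLM	-1	Ex1
94	GBBPAIDLO	-1	Ex1
95	GBBPAIDLB	-1	Ex1
96	GBBPAIDLK	-1	Ex1
97	GBBPAIDEM	-1	Ex1
98	GBBPAIDEL	-1	TRN
99	GBBPAIDEO	-1	Ex1
100	FBBLBIDMJ	-1	TRN
101	FBBKAIDMN	-1	Ex1
102	FBBVAIDEN	+1	TRN
103	HBBTBIDLJ	-1	Ex1
104	HBBTBIDLN	-1	Ex1
105	FBBVAIDEM	+1	Ex1
106	HBBTBIDEN	+1	Ex1
107	HBBTBIDEM	+1	TRN
108	HBBTAIDLJ	-1	TRN
109	HBBTAIDLN	-1	Ex1
110	HABTBIDLJ	-1	Ex1
111	HABTBIDLN	-1	Ex1
112	FBAEAIDLF	-1	Ex1
113	FBAEAIDLG	-1	Ex1
114	FBAEAIDLD	-1	Ex1
115	FBAEAIDLE	-1	Ex1
116	DBBKAIDLJ	-1	Ex1
117	FABOALDLJ	-1	TRN
118	FABPAHDLJ	+1	Ex2
119	FABQBIDLJ	-1	Ex2
120	FABPAJDLJ	+1	Ex2
121	FABSBIDLJ	-1	Ex2
122	FABMBIDLJ	-1	Ex2
123	FABIBIDLJ	-1	Ex2
124	FAAEBIDLH	-1	Ex2
125	FAAEBIDLI	-1	Ex2
126	FAAEBBDLJ	-1	Ex2
127	BABUAIDLN	-1	Ex2
128	BABUAIDEN	-1	Ex2
129	ABBFAIELL	-1	Ex2
130	ABBFAIELJ	-1	Ex2
131	EBBLBIDLJ	-1	Ex2
132	FABFAIDLJ	-1	Ex2
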