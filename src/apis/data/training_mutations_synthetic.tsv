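# SYNTHETIC stand-in training mutation table: residue identities and
# ddG values are generated, not experimental; the class composition
# (62 hot / 92 non-hot under ddG >= 2.0 / < 0.4 kcal/mol) matches the
# published training set. Regenerate with
# scripts/generate_reference_data.py
pdb_id	chain	seq_num	wild_type	ddg
1ahw	B	26	SER	-0.134
1dvf	A	179	GLY	-0.201
3hfm	A	42	THR	3.927
1fcc	A	78	ARG	3.627
1a4y	A	248	THR	-0.225
2ptc	A	195	VAL	0.140
1brs	A	177	HIS	0.390
1gc1	A	70	SER	3.885
1ahw	B	41	GLY	3.352
1a22	B	46	MET	-0.421
1gc1	A	234	GLY	0.038
1jrh	B	52	ILE	0.045
3hfm	A	86	ILE	2.512
1brs	A	101	PHE	5.496
1vfb	B	156	HIS	-0.116
1vfb	B	79	HIS	0.000
2ptc	B	27	SER	-0.020
1ahw	A	31	SER	-0.055
2ptc	A	116	THR	-0.317
2ptc	B	241	MET	3.738
1a4y	A	234	TYR	4.647
1a4y	B	152	LEU	6.802
1jrh	B	160	GLN	3.088
1jrh	B	72	ARG	3.152
1jrh	A	140	CYS	-0.033
2ptc	B	56	VAL	-0.408
2ptc	A	6	SER	-0.081
1dan	A	157	ASP	-0.210
1dvf	B	241	GLY	0.013
1bxi	A	113	PHE	2.759
1fcc	A	143	ASP	-0.288
1bxi	B	56	ARG	3.871
1dvf	B	160	HIS	-0.270
1brs	B	45	GLY	-0.258
1fc2	A	66	VAL	6.136
1gc1	A	246	MET	2.889
1fc2	B	46	ASN	-0.432
1gc1	A	15	THR	2.587
1cbw	B	140	VAL	3.837
1jrh	B	139	ASP	0.283
1bxi	A	170	ILE	5.840
1cbw	A	129	GLY	6.322
1jrh	B	118	PRO	0.284
1dan	B	160	HIS	-0.283
1fcc	A	8	GLU	6.807
1brs	B	140	GLU	-0.465
1cbw	A	164	HIS	3.944
3hfm	A	41	ARG	3.578
1bxi	B	159	TRP	0.062
1a4y	A	82	CYS	7.101
3hfm	A	102	SER	4.757
1dvf	B	7	TYR	2.678
1dan	A	218	SER	5.391
2ptc	A	51	SER	8.362
1jrh	A	216	ARG	-0.280
1cbw	B	86	SER	-0.443
1gc1	A	111	VAL	-0.154
1brs	B	225	LYS	-0.241
1a4y	B	150	SER	-0.011
1dvf	B	71	SER	0.368
1brs	A	122	TYR	4.120
1cbw	A	30	VAL	0.330
2ptc	A	225	PRO	2.954
1a22	A	17	ASP	-0.453
1brs	B	189	TYR	9.663
1fc2	B	13	GLN	0.345
1jrh	A	187	TRP	7.177
1jrh	A	72	MET	3.008
1a22	A	132	ARG	0.224
1dvf	A	220	VAL	-0.206
1fcc	B	163	LEU	-0.064
1vfb	A	176	SER	0.050
1vfb	A	95	PRO	3.028
1jrh	A	71	GLN	-0.035
1gc1	B	30	PHE	4.390
1brs	B	154	SER	-0.413
1brs	A	40	ASN	0.174
2ptc	B	155	PRO	-0.043
1vfb	B	147	ASP	-0.167
1bxi	A	246	ARG	0.097
1fcc	A	172	PRO	-0.211
1gc1	A	217	TRP	5.243
1fc2	B	127	VAL	0.113
1a4y	A	6	VAL	-0.432
3hfm	A	214	PHE	-0.084
2ptc	A	248	VAL	5.981
1fcc	B	224	LEU	0.107
1fcc	A	38	SER	-0.005
1ahw	A	133	SER	2.373
1fcc	B	6	ASN	6.843
1bxi	A	206	LEU	4.618
1gc1	A	136	LYS	4.536
1ahw	B	64	ASN	0.294
1a22	A	240	LYS	-0.481
1fcc	B	9	SER	4.158
2ptc	B	192	HIS	7.320
1jrh	A	8	HIS	4.235
1brs	B	246	LEU	2.767
1a4y	A	185	VAL	0.258
1a4y	A	118	ILE	2.982
1gc1	A	102	TRP	-0.440
1ahw	A	11	VAL	0.235
1cbw	B	215	THR	-0.359
1a4y	B	140	PHE	-0.144
1brs	A	129	GLU	-0.105
1fc2	B	21	SER	5.322
3hfm	B	84	ARG	0.016
3hfm	A	57	SER	6.556
1vfb	A	158	GLY	-0.146
1cbw	B	25	ILE	-0.209
1bxi	A	33	GLU	0.228
1jrh	B	167	PHE	0.365
1a22	A	63	ARG	3.015
1jrh	A	20	HIS	4.980
1jrh	A	110	GLY	-0.020
1bxi	B	34	GLY	0.294
1vfb	A	39	SER	6.314
1gc1	A	186	PRO	-0.256
1fc2	B	106	GLU	0.089
1vfb	B	150	GLN	4.200
1jrh	B	163	PRO	-0.079
1gc1	A	138	LYS	2.552
1a4y	B	96	ARG	-0.359
1brs	A	198	VAL	-0.499
1fcc	A	92	ILE	0.395
2ptc	B	69	GLY	-0.125
1ahw	B	177	ARG	3.113
2ptc	B	126	ASP	-0.354
1vfb	B	173	ILE	0.358
1a4y	B	28	THR	3.016
1ahw	A	169	LEU	0.164
1a22	B	147	ASP	4.017
1fc2	B	157	ARG	-0.139
1ahw	A	98	GLN	0.339
1dvf	A	157	HIS	0.171
1bxi	B	239	TRP	4.071
1fcc	A	46	MET	-0.145
1fc2	A	68	ASP	0.055
1dvf	A	156	HIS	4.535
3hfm	B	120	LYS	0.091
1fcc	A	183	GLU	-0.014
1fcc	A	24	TYR	4.611
1bxi	A	64	ASN	3.501
1dan	B	163	TRP	0.006
1fcc	B	169	PRO	0.382
1a4y	A	152	MET	-0.151
1fcc	B	100	TRP	4.639
1jrh	A	227	LYS	0.055
1a22	B	248	GLN	-0.290
1fc2	A	183	PRO	5.451
1jrh	B	236	ASN	0.001
3hfm	A	107	GLY	-0.313
1dan	A	120	HIS	8.292
3hfm	B	124	ASN	-0.371
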