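residue_number	residue_name	rdc_hz
17	ILE	-21.25
19	GLU	4.117647
20	VAL	13.71324
23	ARG	-2.61029
27	LEU	-7.79412
28	SER	40.40441
33	GLY	-9.11765
36	GLY	-0.29412
42	PHE	18.23529
43	ASP	-14.9632
56	SER	-7.79412
57	ARG	-1.94853
60	GLN	-15.8456
61	SER	-12.5368
81	GLU	38.75
91	THR	-6.47059
93	ALA	-13.75
94	ARG	18.56618
97	GLU	-4.70588
98	GLU	9.522059
99	PHE	12.83088
101	ASP	-8.18015
129	PHE	-2.83088
296	ARG	-21.1397
297	ILE	16.13971
298	THR	29.15441
300	ALA	-30.9559
306	ALA	-5.42279
309	ALA	-25.1654
310	GLN	7.647059
317	GLU	41.39706
319	VAL	13.60294
321	ASP	26.17647
330	ARG	-20.1471
331	ASP	27.44485
332	LEU	-9.33824
333	LEU	13.82353
335	ASP	-30.3493
343	ASP	-26.5441
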