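residue_number	residue_name
4	GLU
5	ARG
10	ARG
12	GLU
15	LYS
19	GLU
22	GLU
23	ARG
43	ASP
45	LYS
49	ARG
53	LYS
54	LYS
57	ARG
66	LYS
67	ARG
70	ARG
71	GLU
73	ARG
76	LYS
79	LYS
81	GLU
88	ASP
94	ARG
97	GLU
98	GLU
101	ASP
112	ASP
118	LYS
121	LYS
124	ASP
125	ASP
136	ARG
139	LYS
145	ASP
149	ARG
150	ASP
152	LYS
160	GLU
161	ASP
163	GLU
165	LYS
168	ASP
173	ARG
176	ASP
177	ASP
178	GLU
186	ARG
189	ARG
192	GLU
205	ASP
215	GLU
220	ARG
227	ASP
230	ASP
233	LYS
237	ARG
245	GLU
248	LYS
249	LYS
253	GLU
256	ARG
267	LYS
283	ASP
286	GLU
287	LYS
292	ASP
294	ASP
295	LYS
296	ARG
313	ASP
315	ASP
316	ASP
317	GLU
321	ASP
324	ASP
328	GLU
330	ARG
331	ASP
335	ASP
336	GLU
338	LYS
343	ASP
344	GLU
354	ASP
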