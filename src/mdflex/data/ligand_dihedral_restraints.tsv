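a_i	a_j	a_k	a_l	phi_deg	force_constant
CB5	CB4	CC5	CC4	42.99	4184
CB5	CB4	CC5	NC1	-138.65	4184
CB3	CB4	CC5	CC4	-136.12	4184
CB3	CB4	CC5	NC1	42.23	4184
CD1	CD6	CC4	NC3	56.05	4184
CD1	CD6	CC4	CC5	-124.05	4184
CD5	CD6	CC4	NC3	-122.52	4184
CD5	CD6	CC4	CC5	57.38	4184
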