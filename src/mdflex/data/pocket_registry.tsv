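pocket_name	lining_residues	atp_site
aD-L13	118,183,221	0
L4-L7	81,82,83,84,86	0
P-aC	67,74,171	0
aG-L14	222,237,273	0
aE-L16	140,317,320	0
aE-L16b	125,132,311	0
P-L12	193,197,199	0
L12	177,185,194	0
aE-b7	116,126,162	0
aC-aL16	73,76,344	0
b5-aL16	88,92,346	0
P-L16	145,146,70,325,326	0
MKI	242,249,259	0
ATP	34,35,169,109	1
aE-aF	142,202,299	0
aH-MKI	241,269,289	0
aF-aG	207,214,235	0
b2-L4	16,17,57	0
aE-L4	82,134,137	0
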