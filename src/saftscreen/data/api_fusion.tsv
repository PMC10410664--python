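api	polymorph	T_m	dH_fus	dCp_a	dCp_b
GSF	I	491.85	37.90	93.84	0.0
IBP	I	348.55	26.40	176.16440	-0.3449480
IMC	gamma	433.35	38.10	238.18385	-0.2785901
NPX	I	429.25	32.40	99.30	0.0
NIF	alpha	445.75	39.30	121.22	0.0
PCM	I	442.55	28.00	99.80	0.0
SIM	I	412.45	27.75	278.77100	-0.331300
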