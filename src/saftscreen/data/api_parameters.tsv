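api	strategy	m_over_M	sigma	u_over_kB	epsHB_over_kB	kappaHB	n_donor	n_acceptor
GSF	REF	0.040179	3.3720	221.26	1985.49	0.02	2	2
IBP	REF	0.012226	4.4320	374.65	879.42	0.03	2	2
IBP	ALT	0.026365	4.0179	309.40	516.47	0.089457	2	2
IMC	REF	0.039920	3.5350	262.79	886.40	0.02	3	3
IMC	ALT	0.022072	3.8225	374.51	1295.43	0.011350	3	3
NPX	REF	0.035200	2.9390	229.45	934.20	0.02	2	2
NPX	ALT	0.019162	4.1142	470.92	1202.65	0.009524	2	2
NIF	REF	0.023470	3.5810	309.44	1221.58	0.02	2	2
PCM	REF	0.049775	3.5080	398.28	1994.23	0.01	2	2
PCM	ALT	0.021406	3.9819	432.09	1635.92	0.054320	2	2
SIM	REF	0.010695	3.0711	296.07	1449.58	0.01	3	3
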