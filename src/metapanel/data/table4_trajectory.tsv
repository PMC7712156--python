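quantity	stat	asd_week0	asd_week3	asd_week10	asd_week18	td_week0
Imidazole Propionate	median	0.37	0.55	0.29	0.14	0.12
Imidazole Propionate	q25	0.19	0.08	0.08	0.03	0.09
Imidazole Propionate	q75	3.38	8.57	0.80	0.46	0.29
Hydroxyproline	median	0.96	1.06	1.27	0.80	0.60
Hydroxyproline	q25	0.72	0.42	0.24	0.54	0.29
Hydroxyproline	q75	4.83	3.67	3.34	3.60	1.20
Theobromine	median	0.89	0.47	0.47	0.47	0.46
Theobromine	q25	0.47	0.47	0.16	0.43	0.34
Theobromine	q75	2.38	1.68	0.47	0.47	0.64
2-hydroxy-3-methylvalerate	median	0.53	0.43	0.34	0.52	0.44
2-hydroxy-3-methylvalerate	q25	0.43	0.18	0.06	0.21	0.21
2-hydroxy-3-methylvalerate	q75	0.75	0.56	0.50	0.63	0.61
Indole	median	1.13	0.66	0.85	0.86	0.39
Indole	q25	0.25	0.32	0.18	0.26	0.15
Indole	q75	1.83	1.75	1.86	1.52	0.59
Adenosine	median	0.67	0.77	0.73	0.57	0.40
Adenosine	q25	0.36	0.50	0.47	0.26	0.18
Adenosine	q75	0.88	1.01	0.90	0.86	0.86
OFM-I deviation score	median	3.90	1.90	1.84	1.73	0.46
OFM-I deviation score	q25	2.33	0.72	0.90	0.71	0.21
OFM-I deviation score	q75	5.72	9.52	3.71	2.62	1.35
OFM-I type II error	percent	5	53	50	56
OFM-A deviation score	median	3.51	2.87	2.18	1.36	0.62
OFM-A deviation score	q25	2.28	1.13	1.07	0.54	0.35
OFM-A deviation score	q75	5.73	9.43	4.18	2.44	1.05
OFM-A type II error	percent	5	53	39	56
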