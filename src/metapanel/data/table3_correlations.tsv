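panel_metabolite	partner	r	p	p_censored
Indole	Carnitine	0.67	0.001	1
Indole	Indole-lactate	0.56	0.001	1
Indole	Saccharopine	0.42	0.007	0
Indole	Stearoyl-carnitine	0.39	0.015	0
Indole	3-(3-hydroxyphenyl)propionate	0.33	0.043	0
Indole	Oxalate	0.33	0.043	0
Imidazole Propionate	Galactonate	0.78	0.001	1
Imidazole Propionate	Gulonate	0.76	0.001	1
Imidazole Propionate	Palmitoyl-carnitine	0.72	0.001	1
Imidazole Propionate	Saccharopine	0.70	0.001	1
Imidazole Propionate	Phosphocholine	0.69	0.001	1
Imidazole Propionate	Cystathionine	0.62	0.001	1
Imidazole Propionate	Phenethylamine	0.61	0.001	1
Imidazole Propionate	Betaine	0.61	0.001	1
Imidazole Propionate	3-(4-hydroxyphenyl)lactate	0.60	0.001	1
Imidazole Propionate	N-propionyl-methionine	0.58	0.001	1
Imidazole Propionate	N-palmitoyl-sphingosine	0.41	0.011	0
Imidazole Propionate	3,5-dihydroxybenzoic	0.40	0.014	0
Imidazole Propionate	3-(3-hydroxyphenyl)propionate	0.39	0.017	0
Imidazole Propionate	Stearoyl-carnitine	0.38	0.018	0
Imidazole Propionate	1-palmitoylglycerol	0.37	0.023	0
Imidazole Propionate	Gamma-glutamyl-histidine	0.36	0.027	0
Imidazole Propionate	Biliverdin	0.34	0.037	0
Imidazole Propionate	Carnitine	0.32	0.048	0
Adenosine	Adenine	0.74	0.001	1
Adenosine	2'-deoxyadenosine	0.54	0.001	1
Adenosine	5-hydroxylysine	0.36	0.0254	0
Adenosine	Hydroxyproline	0.36	0.0256	0
Adenosine	1-(1-enyl-oleoyl)-GPE	0.34	0.0366	0
Hydroxyproline	2-hydroxy-3-methylvalerate	0.61	0.001	1
Hydroxyproline	delta-tocopherol	0.41	0.011	0
Hydroxyproline	2'-deoxyadenosine	0.38	0.017	0
Hydroxyproline	Adenosine	0.36	0.026	0
Hydroxyproline	Copro-stanol	0.36	0.026	0
Hydroxyproline	5alpha-androstan-3beta,17alpha-diol	0.35	0.030	0
Hydroxyproline	p-cresol	-0.32	0.050	0
Hydroxyproline	Betaine	-0.33	0.043	0
Hydroxyproline	Oxalate	-0.35	0.031	0
Hydroxyproline	N-palmitoyl-sphingosine	-0.37	0.023	0
2-hydroxy-3-methylvalerate	Gulonate	0.81	0.001	1
2-hydroxy-3-methylvalerate	Imidazole propionate	0.79	0.001	1
2-hydroxy-3-methylvalerate	Galactonate	0.78	0.001	1
2-hydroxy-3-methylvalerate	Phosphocholine	0.75	0.001	1
2-hydroxy-3-methylvalerate	5-hydroxylysine	0.72	0.001	1
2-hydroxy-3-methylvalerate	Hydroxyproline	0.61	0.001	1
2-hydroxy-3-methylvalerate	Betaine	0.60	0.001	1
2-hydroxy-3-methylvalerate	Phenethylamine	0.59	0.001	1
2-hydroxy-3-methylvalerate	1-(1-enyl-oleoyl)-GPE (P-18:1)	0.55	0.001	1
2-hydroxy-3-methylvalerate	Cystathionine	0.53	0.001	1
2-hydroxy-3-methylvalerate	1-palmitoylglycerol (16:0)	0.51	0.001	1
2-hydroxy-3-methylvalerate	Biliverdin	0.51	0.001	0
2-hydroxy-3-methylvalerate	Propionyl-glycine (C3)	0.45	0.005	0
2-hydroxy-3-methylvalerate	3-(4-hydroxyphenyl)lactate (HPLA)	0.43	0.008	0
2-hydroxy-3-methylvalerate	3-(3-hydroxyphenyl)propionate	0.34	0.039	0
2-hydroxy-3-methylvalerate	Delta-tocopherol	-0.33	0.042	0
2-hydroxy-3-methylvalerate	Copro-stanol	-0.35	0.033	0
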