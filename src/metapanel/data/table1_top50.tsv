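rank	metabolite	auroc_week0	auroc_week18	change_p	subpathway
1	Carnitine	0.77	0.68		Carnitine Metabolism
2	Sphingosine	0.75	0.58		Sphingolipid Metabolism
3	2'-deoxyadenosine	0.75	0.59	0.02	Purine Metabolism, Adenine containing
4	Indole	0.74	0.72		Tryptophan Metabolism
5	Adenine	0.74	0.81		Purine Metabolism, Adenine containing
6	N-stearoyl-sphingosine (d18:1/18:0)	0.73	0.61		Sphingolipid Metabolism
7	Imidazole Propionate	0.71	0.64		Histidine Metabolism
8	10-nonadecenoate (19:1n9)	0.71	0.59	0.01	Long Chain Fatty Acid
9	p-cresol sulfate	0.71	0.53		Phenylalanine and Tyrosine Metabolism
10	Cystathionine	0.71	0.65		Methionine, Cysteine, SAM and Taurine Metabolism
11	5alpha-androstan-3beta,17alpha-diol monosulfate (1)	0.71	0.63	0.01	Steroid
12	3-(3-hydroxyphenyl)propionate	0.71	0.66		Phenylalanine and Tyrosine Metabolism
13	1-(1-enyl-oleoyl)-GPE (P-18:1)	0.71	0.87		Lysoplasmalogen
14	Deoxy-carnitine	0.71	0.58		Carnitine Metabolism
15	Gamma-glutamyl-histidine	0.71	0.68		Gamma-glutamyl Amino Acid
16	Diaminopimelate	0.70	0.62		Food Component/Plant
17	Tyramine O-sulfate	0.70	0.70		Phenylalanine and Tyrosine Metabolism
18	Gulonate	0.70	0.53		Ascorbate and Aldarate Metabolism
19	gamma-tocotrienol	0.70	0.62		Tocopherol Metabolism
20	4-hydroxyphenylacetate	0.70	0.56		Phenylalanine and Tyrosine Metabolism
21	Delta-tocopherol	0.70	0.53		Tocopherol Metabolism
22	Phenethylamine	0.69	0.55		Phenylalanine and Tyrosine Metabolism
23	Propionyl-glycine (C3)	0.69	0.61		Sphingolipid Metabolism
24	N-acetyl-sphingosine	0.69	0.63		Sphingolipid Metabolism
25	Betaine	0.69	0.60		Glycine, Serine and Threonine Metabolism
26	Adenosine	0.69	0.65		Purine Metabolism, Adenine containing
27	Ornithine	0.68	0.51		Urea cycle; Arginine and Proline Metabolism
28	N-palmitoyl-sphingosine (d18:1/16:0)	0.68	0.54	0.03	Sphingolipid Metabolism
29	Galactonate	0.68	0.67		Fructose, Mannose and Galactose Metabolism
30	N1-Methyl-2-pyridone-5-carboxamide	0.68	0.74		Nicotinate and Nicotinamide Metabolism
31	1-palmitoylglycerol (16:0)	0.68	0.54		Monoacylglycerol
32	Phosphocholine	0.67	0.59		Phospholipid Metabolism
33	Theobromine	0.67	0.62	0.02	Xanthine Metabolism
34	3,5-dihydroxybenzoic acid	0.67	0.60		Food Component/Plant
35	Hydroxyproline	0.67	0.56		Urea cycle; Arginine and Proline Metabolism
36	l-urobilin	0.67	0.60	0.02	Hemoglobin and Porphyrin Metabolism
37	carboxyethyl-GABA	0.67	0.55		Glutamate Metabolism
38	oxalate (ethane-dioate)	0.67	0.53		Ascorbate and Aldarate Metabolism
39	Palmitoyl-carnitine (C16)	0.67	0.53		Fatty Acid Metabolism (Acyl Carnitine)
40	Copro-stanol	0.67	0.60		Sterol
41	Saccharopine	0.66	0.57		Lysine Metabolism
42	5-hydroxylysine	0.66	0.53		Lysine Metabolism
43	Stearoyl-carnitine (C18)	0.66	0.58		Fatty Acid Metabolism (Acyl Carnitine)
44	Biliverdin	0.66	0.60		Hemoglobin and Porphyrin Metabolism
45	3-(4-hydroxyphenyl)lactate (HPLA)	0.66	0.59		Phenylalanine and Tyrosine Metabolism
46	Carnosine	0.66	0.57		Dipeptide Derivative
47	10-hydroxystearate	0.66	0.64	0.01	Fatty Acid, Monohydroxy
48	Pentadecanoate (15:0)	0.66	0.55		Long Chain Fatty Acid
49	Hexadecanedioate (C16)	0.66	0.60		Fatty Acid, Dicarboxylate
50	Sphinganine	0.66	0.54		Sphingolipid Metabolism
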