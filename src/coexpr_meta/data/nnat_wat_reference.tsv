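gene	GSE8831	GSE4671	BAIR	DGAP	meta_z	p_value	fdr
GSTT1	0.33	0.92	0.87	0.71	6.16	7.50E-10	4.59E-06
CCDC80	0.36	0.93	0.86		5.82	5.85E-09	3.58E-05
HFE	0.71	0.93	0.71		5.81	6.37E-09	3.90E-05
SOD3	0.64	0.84	0.79	0.51	5.55	2.93E-08	0.0002
NPDC1	0.67	0.92	0.62	0.7	5.44	5.47E-08	0.0003
AQP1	0.68	0.71	0.8	0.47	5.37	7.73E-08	0.0005
EBF1	0.62	0.84	0.81		5.3	1.15E-07	0.0007
SNCG	0.81	0.58	0.72		5.28	1.30E-07	0.0008
LGALS12		0.95	0.83		5.15	2.57E-07	0.0016
SLC6A13	0.73	0.8	0.7	0.4	5.1	3.43E-07	0.0021
HEBP1	0.73	0.84	0.69		5.09	3.53E-07	0.0022
NPR3	0.66	0.71	0.77	0.54	5.07	4.04E-07	0.0025
RAD50	0.63	0.35	0.85		5.06	4.16E-07	0.0025
H6PD	0.54	0.85	0.77	0.53	5.04	4.57E-07	0.0028
HTRA3	0.48	0.95	0.67		5.01	5.76E-07	0.0035
ART3	0.63	0.81	0.77		4.95	7.28E-07	0.0045
CAV1	0.67	0.73	0.78		4.95	7.46E-07	0.0046
AOC3	0.27	0.95	0.76	0.25	4.94	7.73E-07	0.0047
ANXA6	0.65	0.73	0.73	0.57	4.84	1.29E-06	0.0079
CXCL9	0.33	0.53	0.88		4.71	2.51E-06	0.0154
JUP	0.55	0.79	0.62	0.89	4.7	2.60E-06	0.0159
BLCAP	0.5	0.9	0.61	0.76	4.65	3.30E-06	0.0202
FZD4	0.49	0.73	0.79	0.5	4.63	3.62E-06	0.0221
SULF2		0.88	0.86		4.63	3.68E-06	0.0226
CD151		0.83	0.87	0.46	4.62	3.79E-06	0.0232
MAP1LC3A	0.68	0.78	0.59	0.67	4.56	5.05E-06	0.0309
EPN2	0.54	0.91	0.53	0.71	4.48	7.42E-06	0.0454
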