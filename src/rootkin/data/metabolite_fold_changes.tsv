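metabolite	R1	R2	R3
taurine	6.98	3.83	3.48
proline	18.6	17.87	19.25
ornithine	1.06	1.95	1.83
serine	1.61	1.68	1.74
tyrosine	0.65	0.79	0.89
arginine	0.86	0.82	0.87
citrulline	3.7	3.49	3.59
tryptophan	1.07	1.02	1.04
glutamate	1.04	1.24	1.36
saccharopine	20.38	34.64	67.5
GABA	1.83	1.51	1.75
phenylalanine	0.65	0.72	0.76
cysteine	5.59	7.01	8.11
methionine	1.04	1.04	1.26
sucrose	19.53	8.18	8.59
glucose	1.13	1.29	1.4
fructose	1.59	1.84	2.3
raffinose	24.23	34	22.81
myo-inositol	3.71	5.57	6.91
GSH	1.58	8.72	25.02
GSSG	5.91	6.28	8.6
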