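pathway	node_a	node_b
arginine_proline_metabolism	glutamate	ornithine
arginine_proline_metabolism	ornithine	citrulline
arginine_proline_metabolism	citrulline	arginine
arginine_proline_metabolism	glutamate	proline
arginine_proline_metabolism	glutamate	GABA
arginine_proline_metabolism	saccharopine	proline
taurine_hypotaurine_metabolism	serine	cysteine
taurine_hypotaurine_metabolism	cysteine	taurine
glutathione_metabolism	cysteine	GSH
glutathione_metabolism	glutamate	GSH
glutathione_metabolism	GSH	GSSG
starch_sucrose_metabolism	sucrose	glucose
starch_sucrose_metabolism	sucrose	fructose
starch_sucrose_metabolism	sucrose	raffinose
starch_sucrose_metabolism	raffinose	myo-inositol
aromatic_amino_acid_metabolism	phenylalanine	tyrosine
aromatic_amino_acid_metabolism	phenylalanine	tryptophan
cysteine_methionine_metabolism	serine	cysteine
cysteine_methionine_metabolism	cysteine	methionine
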