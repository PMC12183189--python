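arginine_proline_metabolism	synthetic toy pathway	glutamate	ornithine	citrulline	arginine	proline	GABA	saccharopine
taurine_hypotaurine_metabolism	synthetic toy pathway	serine	cysteine	taurine
glutathione_metabolism	synthetic toy pathway	cysteine	glutamate	GSH	GSSG
starch_sucrose_metabolism	synthetic toy pathway	sucrose	glucose	fructose	raffinose	myo-inositol
aromatic_amino_acid_metabolism	synthetic toy pathway	phenylalanine	tyrosine	tryptophan
cysteine_methionine_metabolism	synthetic toy pathway	serine	cysteine	methionine
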