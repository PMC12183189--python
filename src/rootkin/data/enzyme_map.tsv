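metabolite	step	role	transcripts
proline	glutamate_5_kinase	synthesis	T_G5K
proline	glutamate_5_semialdehyde_dehydrogenase	synthesis	T_G5SADH
proline	proline_dehydrogenase	degradation	T_PRODH
proline	pipecolate_oxidase	competing	T_PIPOX
saccharopine	lysine_ketoglutarate_reductase_saccharopine_dehydrogenase	synthesis	T_LKRSDH
taurine	cysteate_decarboxylase	synthesis	T_TAU1
taurine	hypotaurine_dehydrogenase	synthesis	T_TAU2
GSH	glutathione_reductase	synthesis	T_GR
GSH	glutathione_peroxidase	degradation	T_GPX1
sucrose	sucrose_phosphate_synthase	synthesis	T_SPS
raffinose	raffinose_synthase	synthesis	T_RAFS
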