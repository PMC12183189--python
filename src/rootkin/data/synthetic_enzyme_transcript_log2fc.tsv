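transcript	R1	R2	R3
T_G5K	2.5	2.8	2.6
T_G5SADH	2.1	2.3	2.2
T_PRODH	-2.4	-2.2	-2.6
T_PIPOX	-2.2	-2.5	-2.8
T_LKRSDH	0.2	0.1	0.3
T_TAU1	2.2	2.4	0.8
T_TAU2	1.8	2.0	0.5
T_GR	0.3	1.6	1.8
T_GPX1	0.4	2.3	2.5
T_SPS	0.1	0.2	0.1
T_RAFS	2.6	2.9	2.4
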