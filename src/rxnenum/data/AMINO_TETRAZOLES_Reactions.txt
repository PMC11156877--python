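REACTION	V1	[NX3;H2,H1;!$(NC=O):1].S=C=N[*;!H;!$(C=O):3]>>[*:1](C1=NN=NN1[*:3])	TETR_A,TETR_B
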