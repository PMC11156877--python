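REACTION	V1	[NX3;H2,H1;!$(NC=O):1]>>[N:1]C1=NN=NS1	THIA_A
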