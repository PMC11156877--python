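# 5-amino-thiatriazoles: one-component reaction on primary/secondary amines
# (amide nitrogens vetoed by the !$(NC=O) clause of the inclusion pattern).
SYNTHON	A	[NX3;H2,H1;!$(NC=O)]
EXCLUDE	A	[NX3][NX3]
EXCLUDE	A	[NX3][OX2H1]
TAG	A	THIA_A
# Global reactive/unstable-group exclusions (editable approximation).
EXCLUDE	*	[OX2][OX2]
EXCLUDE	*	N=[N+]=[N-]
EXCLUDE	*	[NX2]=C=[OX1]
EXCLUDE	*	[NX2]=C=[SX1]
EXCLUDE	*	[CX3](=[OX1])[F,Cl,Br,I]
EXCLUDE	*	[CX3](=[OX1])[OX2][CX3](=[OX1])
EXCLUDE	*	[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]
EXCLUDE	*	[NX2]=[OX1]
EXCLUDE	*	[NX3][F,Cl,Br,I]
EXCLUDE	*	[#6;r3][O,N,S;r3]
EXCLUDE	*	[SX2H1]
EXCLUDE	*	[CX4][Cl,Br,I]
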