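# [2+2]-cycloaddition via in-situ cyclic allene: reagent A is an anhydride or
# an acyl chloride (source of the 1,2-acyloxycyclohexadiene intermediate),
# reagent B a mono-substituted (R2=H) or 1,1-disubstituted styrene/electron-
# deficient olefin. Anhydride and acyl-halide rules of the global exclusion
# list are dropped here because those motifs are the reagent-A classes.
SYNTHON	A_ANHYDRIDE	[#6][CX3D3!R](=O)[O!R][CX3D3!R](=O)[#6]
SYMMETRIC	A_ANHYDRIDE	[*:1]C(=O)OC(=O)[*:2]
TAG	A_ANHYDRIDE	CC22_ANH
SYNTHON	A_ACYL_CHLORIDE	[#6][CX3D3!R](=O)Cl
TAG	A_ACYL_CHLORIDE	CC22_ACL
SYNTHON	B_MONOSUB	[CX3H2;!R]=[CX3H1;!R]([$([CX3](=[OX1])[#6,$([OX2][#6])]),$([CX2]#[NX1]),c])
TAG	B_MONOSUB	CC22_B1
SYNTHON	B_DISUB	[CX3H2;!R]=[CX3;!R]([#6])([$([CX3](=[OX1])[#6,$([OX2][#6])]),$([CX2]#[NX1]),c])
TAG	B_DISUB	CC22_B11
EXCLUDE	*	[OX2][OX2]
EXCLUDE	*	N=[N+]=[N-]
EXCLUDE	*	[NX2]=C=[OX1]
EXCLUDE	*	[NX2]=C=[SX1]
EXCLUDE	*	[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]
EXCLUDE	*	[NX2]=[OX1]
EXCLUDE	*	[NX3][F,Cl,Br,I]
EXCLUDE	*	[#6;r3][O,N,S;r3]
EXCLUDE	*	[SX2H1]
EXCLUDE	*	[CX4][Cl,Br,I]
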