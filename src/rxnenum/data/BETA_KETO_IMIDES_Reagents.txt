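# beta-keto-imides: dioxinone (reagent A) + primary/secondary amide (reagent B)
# Reagent A dioxinones are scarce commercially; they are produced in situ from
# beta-keto acids or their O-tBu / O-Me / O-Et / O-Bn esters via one-component
# precursor transforms (synthon A_PRE).
SYNTHON	A	C1([CH3])([CH3])OC(=O)C([H])=CO1
TAG	A	BKI_A
SYNTHON	A_PRE	[OH]C([CH2][C;!R]([C;!c])=O)=O|O=C([CH2][C;!R]([C;!c])=O)OC([CH3])([CH3])[CH3]|O=C([CH2][C;!R]([C;!c])=O)O[CH3]|O=C([CH2][C;!R]([C;!c])=O)O[CH2][CH3]|O=C([CH2][C;!R]([C;!c])=O)O[CH2][c]1[cH1][cH1][cH1][cH1][cH1]1
PRECURSOR	A_PRE	[OX2H1:7][C:1](=[O:2])[CH2:3][C;!R:4](=[O:5])[C;!c:6]>>[O:7]1C(C)(C)[O:5][C:4]([C:6])=[C:3][C:1]1=[O:2]
PRECURSOR	A_PRE	[OX2:7](C([CH3])([CH3])[CH3])[C:1](=[O:2])[CH2:3][C;!R:4](=[O:5])[C;!c:6]>>[O:7]1C(C)(C)[O:5][C:4]([C:6])=[C:3][C:1]1=[O:2]
PRECURSOR	A_PRE	[OX2:7]([CH3])[C:1](=[O:2])[CH2:3][C;!R:4](=[O:5])[C;!c:6]>>[O:7]1C(C)(C)[O:5][C:4]([C:6])=[C:3][C:1]1=[O:2]
PRECURSOR	A_PRE	[OX2:7]([CH2][CH3])[C:1](=[O:2])[CH2:3][C;!R:4](=[O:5])[C;!c:6]>>[O:7]1C(C)(C)[O:5][C:4]([C:6])=[C:3][C:1]1=[O:2]
PRECURSOR	A_PRE	[OX2:7]([CH2]c1ccccc1)[C:1](=[O:2])[CH2:3][C;!R:4](=[O:5])[C;!c:6]>>[O:7]1C(C)(C)[O:5][C:4]([C:6])=[C:3][C:1]1=[O:2]
TAG	A_PRE	BKI_A
SYNTHON	B	[CX3]([NX3;H2,H1])=O
EXCLUDE	B	[CX3](=[OX1])[NX3][CX3](=[OX1])
TAG	B	BKI_B
# Global reactive/unstable-group exclusions (editable approximation, not a
# canonical published list; see docs/methods.md).
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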