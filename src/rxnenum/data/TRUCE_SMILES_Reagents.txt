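# Truce-Smiles rearrangement. Reagent A carries an aromatic ring bearing a
# Z-H group (primary amine, alcohol or thiol: A_ZH) or a primary sulfonamide
# (A_SULFONAMIDE). Reagent B is an acyl halide whose alpha chain places an
# electron-withdrawing group (nitrile, sulfonyl, ketone or ester) 0, 1 or 2
# sp3 CH2 carbons away from the halide carbonyl; B classes split by chain
# length and by whether the EWG-bearing carbon keeps a hydrogen (non-chiral,
# B_H*) or carries a second substituent (chiral products, B_R*).
# Thiol and acyl-halide rules of the global exclusion list are dropped here
# because those motifs are the reactive groups of this reaction.
SYNTHON	A_ZH	a[OX2H1,NX3H2,SX2H1]
TAG	A_ZH	TS_A_ZH
SYNTHON	A_SULFONAMIDE	a[$([SX4](=[OX1])(=[OX1])[NX3H2])]
TAG	A_SULFONAMIDE	TS_A_SA
SYNTHON	B_H0	O=C([Cl,Br,I])[CX4H2!R,CX4H3!R]([$([CX2]#[NX1]),$([SX4](=[OX1])=[OX1]),$([CX3](=[OX1])),$([CX3](=[OX1])[OX2H0])])
TAG	B_H0	TS_B_H0
SYNTHON	B_H1	O=C([Cl,Br,I])[CX4H2][CX4H2!R,CX4H3!R]([$([CX2]#[NX1]),$([SX4](=[OX1])=[OX1]),$([CX3](=[OX1])),$([CX3](=[OX1])[OX2H0])])
TAG	B_H1	TS_B_H1
SYNTHON	B_H2	O=C([Cl,Br,I])[CX4H2][CX4H2][CX4H2!R,CX4H3!R]([$([CX2]#[NX1]),$([SX4](=[OX1])=[OX1]),$([CX3](=[OX1])),$([CX3](=[OX1])[OX2H0])])
TAG	B_H2	TS_B_H2
SYNTHON	B_R0	O=C([Cl,Br,I])[CX4H1!R]([$([CX2]#[NX1]),$([SX4](=[OX1])=[OX1]),$([CX3](=[OX1])),$([CX3](=[OX1])[OX2H0])])
TAG	B_R0	TS_B_R0
SYNTHON	B_R1	O=C([Cl,Br,I])[CX4H2][CX4H1!R]([$([CX2]#[NX1]),$([SX4](=[OX1])=[OX1]),$([CX3](=[OX1])),$([CX3](=[OX1])[OX2H0])])
TAG	B_R1	TS_B_R1
SYNTHON	B_R2	O=C([Cl,Br,I])[CX4H2][CX4H2][CX4H1!R]([$([CX2]#[NX1]),$([SX4](=[OX1])=[OX1]),$([CX3](=[OX1])),$([CX3](=[OX1])[OX2H0])])
TAG	B_R2	TS_B_R2
EXCLUDE	*	[OX2][OX2]
EXCLUDE	*	N=[N+]=[N-]
EXCLUDE	*	[NX2]=C=[OX1]
EXCLUDE	*	[NX2]=C=[SX1]
EXCLUDE	*	[CX3](=[OX1])[OX2][CX3](=[OX1])
EXCLUDE	*	[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]
EXCLUDE	*	[NX2]=[OX1]
EXCLUDE	*	[NX3][F,Cl,Br,I]
EXCLUDE	*	[#6;r3][O,N,S;r3]
EXCLUDE	*	[CX4][Cl,Br,I]
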