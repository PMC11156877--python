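# Twelve transform variants: {Z-H, sulfonamide} reagent A x {chain 0/1/2} x
# {non-chiral R2=H, chiral R2!=H} reagent B. The aryl group migrates from
# reagent A onto the EWG-bearing carbon of reagent B.
REACTION	ZH_H0	[a:1][OX2H1,NX3H2,SX2H1:2].[F,Cl,Br,I][$(C=O):3][CX4H2!R,CX4H3!R:5][H]>>[*:5]([a:1])([$(C=O):3][*:2])	TS_A_ZH,TS_B_H0	reagent_a=ZH,chain=0,chiral=no
REACTION	ZH_H1	[a:1][OX2H1,NX3H2,SX2H1:2].[F,Cl,Br,I][$(C=O):3][CX4H2:6][CX4H2!R,CX4H3!R:5][H]>>[*:5]([a:1])([*:6][$(C=O):3][*:2])	TS_A_ZH,TS_B_H1	reagent_a=ZH,chain=1,chiral=no
REACTION	ZH_H2	[a:1][OX2H1,NX3H2,SX2H1:2].[F,Cl,Br,I][$(C=O):3][CX4H2:7][CX4H2:6][CX4H2!R,CX4H3!R:5][H]>>[*:5]([a:1])([*:7][*:6][$(C=O):3][*:2])	TS_A_ZH,TS_B_H2	reagent_a=ZH,chain=2,chiral=no
REACTION	ZH_R0	[a:1][OX2H1,NX3H2,SX2H1:2].[F,Cl,Br,I][$(C=O):3][CX4H1!R:5]([H])([*:9])>>[*:5]([*:9])([a:1])([$(C=O):3][*:2])	TS_A_ZH,TS_B_R0	reagent_a=ZH,chain=0,chiral=yes
REACTION	ZH_R1	[a:1][OX2H1,NX3H2,SX2H1:2].[F,Cl,Br,I][$(C=O):3][CX4H2:6][CX4H1!R:5]([H])([*:9])>>[*:5]([*:9])([a:1])([*:6][$(C=O):3][*:2])	TS_A_ZH,TS_B_R1	reagent_a=ZH,chain=1,chiral=yes
REACTION	ZH_R2	[a:1][OX2H1,NX3H2,SX2H1:2].[F,Cl,Br,I][$(C=O):3][CX4H2:7][CX4H2:6][CX4H1!R:5]([H])([*:9])>>[*:5]([*:9])([a:1])([*:7][*:6][$(C=O):3][*:2])	TS_A_ZH,TS_B_R2	reagent_a=ZH,chain=2,chiral=yes
REACTION	SA_H0	[a:1][$([SX4](=[OX1])(=[OX1])[NX3H2])].[F,Cl,Br,I][$(C=O):3][CX4H2!R,CX4H3!R:5][H]>>[*:5]([a:1])([$(C=O):3]O)	TS_A_SA,TS_B_H0	reagent_a=sulfonamide,chain=0,chiral=no
REACTION	SA_H1	[a:1][$([SX4](=[OX1])(=[OX1])[NX3H2])].[F,Cl,Br,I][$(C=O):3][CX4H2:6][CX4H2!R,CX4H3!R:5][H]>>[*:5]([a:1])([*:6][$(C=O):3]O)	TS_A_SA,TS_B_H1	reagent_a=sulfonamide,chain=1,chiral=no
REACTION	SA_H2	[a:1][$([SX4](=[OX1])(=[OX1])[NX3H2])].[F,Cl,Br,I][$(C=O):3][CX4H2:7][CX4H2:6][CX4H2!R,CX4H3!R:5][H]>>[*:5]([a:1])([*:7][*:6][$(C=O):3]O)	TS_A_SA,TS_B_H2	reagent_a=sulfonamide,chain=2,chiral=no
REACTION	SA_R0	[a:1][$([SX4](=[OX1])(=[OX1])[NX3H2])].[F,Cl,Br,I][$(C=O):3][CX4H1!R:5]([H])([*:9])>>[*:5]([*:9])([a:1])([$(C=O):3]O)	TS_A_SA,TS_B_R0	reagent_a=sulfonamide,chain=0,chiral=yes
REACTION	SA_R1	[a:1][$([SX4](=[OX1])(=[OX1])[NX3H2])].[F,Cl,Br,I][$(C=O):3][CX4H2:6][CX4H1!R:5]([H])([*:9])>>[*:5]([*:9])([a:1])([*:6][$(C=O):3]O)	TS_A_SA,TS_B_R1	reagent_a=sulfonamide,chain=1,chiral=yes
REACTION	SA_R2	[a:1][$([SX4](=[OX1])(=[OX1])[NX3H2])].[F,Cl,Br,I][$(C=O):3][CX4H2:7][CX4H2:6][CX4H1!R:5]([H])([*:9])>>[*:5]([*:9])([a:1])([*:7][*:6][$(C=O):3]O)	TS_A_SA,TS_B_R2	reagent_a=sulfonamide,chain=2,chiral=yes
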