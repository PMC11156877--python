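# Six variants: {anhydride, acyl chloride} reagent A x {furan,
# cyclopentadiene, pyrrole} diene family.
REACTION	ANH_FURAN	C(=O)(OC=O)[*:1].[c:2]1[o:3][c:4][c:5][c:6]1>>C1(=C2C(CCC1)[C:2]3[O:3][C:4]2[C:5]=[C:6]3)OC(=O)[*:1]	CC42_ANH,CC42_FURAN	reagent_b=furan
REACTION	ACL_FURAN	ClC(=O)[*:1].[c:2]1[o:3][c:4][c:5][c:6]1>>C1(=C2C(CCC1)[C:2]3[O:3][C:4]2[C:5]=[C:6]3)OC(=O)[*:1]	CC42_ACL,CC42_FURAN	reagent_b=furan
REACTION	ANH_CP	C(=O)(OC=O)[*:1].[C:2]=1[C:3][C:4]=[C:5][C:6]1>>C1(=C2C(CCC1)[C:2]3[C:3][C:4]2[C:5]=[C:6]3)OC(=O)[*:1]	CC42_ANH,CC42_CP	reagent_b=cyclopentadiene
REACTION	ACL_CP	ClC(=O)[*:1].[C:2]=1[C:3][C:4]=[C:5][C:6]1>>C1(=C2C(CCC1)[C:2]3[C:3][C:4]2[C:5]=[C:6]3)OC(=O)[*:1]	CC42_ACL,CC42_CP	reagent_b=cyclopentadiene
REACTION	ANH_PYR	C(=O)(OC=O)[*:1].[c:2]1[n:3][c:4][c:5][c:6]1>>C1(=C2C(CCC1)[C:2]3[N:3][C:4]2[C:5]=[C:6]3)OC(=O)[*:1]	CC42_ANH,CC42_PYR	reagent_b=pyrrole
REACTION	ACL_PYR	ClC(=O)[*:1].[c:2]1[n:3][c:4][c:5][c:6]1>>C1(=C2C(CCC1)[C:2]3[N:3][C:4]2[C:5]=[C:6]3)OC(=O)[*:1]	CC42_ACL,CC42_PYR	reagent_b=pyrrole
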