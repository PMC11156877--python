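# Four variants: {anhydride, acyl chloride} reagent A x {R2=H, R2!=H} olefin.
# The anhydride and acyl-chloride transforms share their product template; the
# olefin class is selected by the component tag.
REACTION	ANH_B1	C(=O)(OC=O)[*:1].[CX3H2]=C([*:2])([*:3])>>C1(=C2C(CCC1)C(C2)([*:2])[*:3])OC([*:1])=O	CC22_ANH,CC22_B1	reagent_b=monosub
REACTION	ACL_B1	ClC(=O)[*:1].[CX3H2]=C([*:2])([*:3])>>C1(=C2C(CCC1)C(C2)([*:2])[*:3])OC([*:1])=O	CC22_ACL,CC22_B1	reagent_b=monosub
REACTION	ANH_B11	C(=O)(OC=O)[*:1].[CX3H2]=C([*:2])([*:3])>>C1(=C2C(CCC1)C(C2)([*:2])[*:3])OC([*:1])=O	CC22_ANH,CC22_B11	reagent_b=disub
REACTION	ACL_B11	ClC(=O)[*:1].[CX3H2]=C([*:2])([*:3])>>C1(=C2C(CCC1)C(C2)([*:2])[*:3])OC([*:1])=O	CC22_ACL,CC22_B11	reagent_b=disub
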