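# beta-keto-imide condensation: dioxinone + primary/secondary amide.
# The acetonide-derived by-product on the product side is discarded by the
# enumerator (largest-fragment rule).
REACTION	V1	[O:1]=C1[O:2][C:6](C)(C)[O:3]C([*,H:22])=C1[*,H:21].[*,H:23]C([N:5]([H:99])[*,H:24])=[O:4]>>[O:4]=C([*,H:23])[N:5]([*,H:24])C(C([*,H:21])C([*,H:22])=[O:3])=[O:1].[H:99][O:2][C:6](C)C	BKI_A,BKI_B
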