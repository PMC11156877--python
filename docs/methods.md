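# Methods

`rxnenum` is a toolkit for building make-on-demand virtual chemical
libraries from SMARTS-encoded reactions and tiered commercial
building-block catalogs. This note records the models, conventions and
numerical choices behind each stage, the assumptions the synthetic fixture
data does and does not exercise, and the known limitations.

## Reaction model

A reaction definition couples **synthons** with **transform variants**.

A synthon is a reagent class: a disjunction of inclusion SMARTS (a molecule
qualifies if any pattern matches), synthon-specific exclusion SMARTS, an
optional symmetry pattern (e.g. `[*:1]C(=O)OC(=O)[*:2]` for anhydrides,
where the two acyl sides are interchangeable), and one or more *reaction
tags* that name the reagent slots the class can feed. A variant is one
atom-mapped reaction SMARTS plus an ordered list of component tags (one per
reagent template). R-group constraints of the underlying chemistry (chain
lengths, electron-withdrawing groups, steric hindrance, chirality classes)
are expressed entirely inside the SMARTS; variants carry free-form
annotations (`chain=1`, `chiral=yes`, ...) for provenance only.

Six definitions ship as built-ins, stored in the same two-file text format
the parser accepts (`src/rxnenum/data/*_Reagents.txt` /
`*_Reactions.txt`):

| reaction | components | variants |
|---|---|---|
| beta-keto-imides | dioxinone + 1°/2° amide | 1 (+5 precursor transforms) |
| 5-amino-thiatriazoles | 1°/2° amine | 1 |
| 5-amino-tetrazoles | amine + isothiocyanate | 1 |
| Truce-Smiles rearrangement | aryl Z–H or sulfonamide + EWG acyl halide | 12 |
| [2+2]-cycloaddition | anhydride/acyl chloride + olefin | 4 |
| [4+2]-cycloaddition | anhydride/acyl chloride + furan/cyclopentadiene/pyrrole | 6 |

### Precursor synthons

Dioxinones are scarce commercially, so the beta-keto-imide definition
carries a *precursor* synthon matching free β-keto acids and their
O-tBu/O-Me/O-Et/O-Bn esters, with five one-component transforms converting
each form into the reactive 2,2-dimethyl-dioxin-4-one. The five transforms
were authored for this package; their products are verified in tests to
match the dioxinone inclusion pattern. A precursor synthon shares the
reaction tag of the slot it feeds; tag resolution for variant slots is
scoped to non-precursor synthons, so each tag still resolves uniquely. The
enumerator expands precursor pools before combination, and derived reagents
inherit the vendor ID and price tier of their purchasable precursor (with a
`.k` suffix when one precursor yields several distinct reagents).

### Hydrogen handling in transforms

The encoded transforms are heterogeneous in their hydrogen conventions:
some contain literal mapped hydrogens (`[H:99]`) or wildcards that must
bind a hydrogen (`[*:3]` on a mono-substituted olefin carbon), which only
match molecules with explicit hydrogens, while others (the amine-consuming
heterocyclizations) assume implicit hydrogens and produce nitrogen valence
errors when hydrogens are explicit. `apply_variant` therefore runs every
reagent tuple twice — as parsed and with explicit hydrogens added — merges
the outcomes, and silently drops raw products that fail sanitization. This
is deterministic and conservative: a product appears iff at least one
convention yields a chemically valid structure.

### By-products and uniqueness

Several transforms emit leaving-group fragments on the product side (the
acetonide-derived fragment of the beta-keto-imide condensation). Per raw
product set we keep only the fragment with the most heavy atoms, breaking
ties by lexicographically smallest canonical SMILES. Products are
enumerated in 2D (no stereo descriptors are assigned; the Truce-Smiles
"chiral" variants record their chirality class as an annotation only) and
deduplicated on the standard InChIKey. The default dedup scope is one
reaction; a shared `seen` set extends it across reactions.

## Building-block filtering

Catalog entries are standardized by keeping the largest organic fragment
(salt stripping; recorded on the block), then filtered per synthon:
inclusion (any-of), synthon exclusions, reaction-global exclusions, and a
40-heavy-atom cap applied *after* salt stripping. All distinct embeddings
of the inclusion pattern are retained on the match, so multi-site reagents
(diamines) can form every product; uniqueness is restored downstream by
InChIKey dedup. Substructure matching runs on explicit-hydrogen copies
because two printed inclusion patterns contain literal `[H]` atoms; SMARTS
total-H counts (`H2`, `X3` etc.) are unaffected by this choice.

Price tiers follow the five-group BB-50 … BB-10 convention; *cheap* means
BB-50 ∪ BB-40. Product purchasability is coded 1 (all reagents BB-50), 2
(all cheap, ≥1 BB-40) or expensive. A vendor ID listed under several tiers
keeps the cheapest.

The reaction-global exclusion lists packaged with the definitions are an
editable 12-rule approximation of common reactive/unstable-group filters
(peroxides, azides, isocyanates/isothiocyanates, acyl and sulfonyl
halides, anhydrides, nitroso, N-halogen, strained three-membered
heterocycles, thiols, alkyl halides), pruned per reaction so that a rule
never vetoes that reaction's own reagent class (e.g. the isothiocyanate
rule is dropped for the tetrazole reaction). They are **not** a canonical
published list and can be edited in the data files.

## Descriptors and gates

Descriptors are computed on the canonicalized structure (so records are a
pure function of the molecule, untouched by input atom ordering): molecular
weight (Da), Crippen atom-contribution cLogP, Lipinski hydrogen-bond counts
(HBA = N+O, HBD = NH+OH), rotatable bonds, TPSA (Å²), heavy-atom count,
Fsp3 and QED. The druglike gate is the conjunction MW ≤ 500, cLogP ≤ 5,
HBA ≤ 10, HBD ≤ 5, ROTB ≤ 10, TPSA ≤ 140, plus a heavy-atom cap of 38 that
is configurable (`hac_cap=None` disables it) but on by default; all bounds
inclusive, so the gate is monotone non-increasing in every descriptor.
The Lipinski N/O counting convention (rather than pharmacophore acceptor
definitions) was chosen for reproducibility of the gate; the alternative
would shift HBA on sulfonyl/aromatic-N compounds.

Structural alerts use the published PAINS (split A/B/C), Brenk and NIH
substructure catalogs via RDKit's FilterCatalog; a flag is set iff at least
one pattern of that catalog matches, and the flags are mutually
independent. `alert_rates` reports per-catalog counts and fractions with
the denominator.

## Diversity analytics

**Scaffolds.** Bemis-Murcko frameworks (ring systems + linkers, side chains
removed) are computed with the standard Murcko-scaffold reduction. Acyclic
molecules, for which the framework is undefined, are counted under an
empty-scaffold sentinel, reported separately, and excluded from scaffold
counts and overlap. Overlap between two censuses is plain set intersection
of canonical scaffold SMILES, reported as a count and as a fraction of
each side.

**Shape.** One conformer per molecule is generated by distance-geometry
embedding with a fixed seed (default 42; random-coordinate fallback on
failure). Principal moments of inertia I1 ≤ I2 ≤ I3 are computed from the
mass-weighted inertia tensor of the conformer by eigendecomposition — our
own implementation, cross-checked in tests against RDKit's NPR
descriptors to 1e-6 — and reported as NPR1 = I1/I3, NPR2 = I2/I3. Valid
shapes satisfy NPR1 ≤ NPR2 ≤ 1 and NPR1+NPR2 ≥ 1 (rod (0,1), disc
(0.5,0.5), sphere (1,1)). Populations are binned on a 200×200 grid over
NPR1 ∈ [0,1] × NPR2 ∈ [0.5,1]; points outside the triangle by more than
1e-6 are clamped onto it with a warning. Multi-conformer averaging is out
of scope; single-embed shapes are noisy for flexible molecules and should
be read as population statistics, not per-molecule truths.

**Identity search.** Library membership uses the full 27-character standard
InChIKey (the conservative reading — the 14-character skeleton would
conflate tautomer/isotope variants). Keys are partitioned by
(heavy-atom count, first two key letters) into sorted buckets, persisted as
a `grep`-friendly `<hac>/<prefix>.txt` tree; lookups are bisections within
one bucket and are tested to agree exactly with a linear scan. Heavy atoms
are counted on the standardized (salt-stripped, canonical) structure.

## Synthetic fixture data

`generate_fixtures` emits building blocks for the fourteen reagent classes
the six reactions consume. Candidates come from curated per-class fragment
grammars — small alkyl/aryl decorations on the class core motif (e.g.
`O=C(Cl){chain}{center}{EWG}` for the Truce-Smiles acyl halides) — so
membership holds by construction; every emitted block is still verified
against the packaged inclusion/exclusion SMARTS and the heavy-atom cap, and
generation raises rather than under-delivering. Tiers are drawn from a
configurable mix (default 40/30/15/10/5% for BB-50…BB-10) with the spec's
seed; vendor IDs are `FIX-<class>-<i>`. Typical test pools are 5–6 blocks
per class, giving 25–200 products per reaction and ~800 over all six.

What the fixtures do **not** emulate: the scale (millions of blocks),
the skew and redundancy of real vendor catalogs, counterions and
stereo-annotated SMILES, exotic protecting groups, or molecules near the
40-heavy-atom boundary in bulk. Passing tests therefore demonstrate
correctness of the filtering/enumeration/analytics logic, not the
throughput or the catalog-dependent composition numbers of a production
library build; headline counts from billion-scale builds are expressly not
reproduced at this scale.

## Numerical and engineering choices

- `chunk_size` (default 2000) controls how the first reagent pool is
  blocked during enumeration; results are invariant to it (tested), so it
  is purely an execution-shape knob for distributing work.
- MaxMin curation picks use 2048-bit radius-2 Morgan (ECFP4-like)
  fingerprints with Tanimoto distance; the pick is deterministic given the
  seed. Greedy MaxMin is an approximation: it matches an independent greedy
  reference exactly but can fall short of the exhaustive-subset optimum.
- Unparseable catalog SMILES are skipped with a log record, never fatal;
  unparseable SMARTS in definition files are hard errors with line numbers.
- CSV floats are serialized to 6 significant digits; writers embed no
  timestamps, so all file outputs are bit-reproducible.
- Degenerate inputs: empty reagent pools warn and yield an empty stream;
  `curation_sample(k > n)` warns and returns everything; a collapsed
  (zero-inertia) point set raises.

## Known limitations

- Stereochemistry is not enumerated; chiral product classes are annotated,
  not resolved into enantiomers.
- The global exclusion lists are an approximation (above), so absolute
  alert/filter pass rates on real catalogs will differ from a build using a
  vendor's own rule set.
- Whether a compound reachable by two different reactions should be
  deduplicated across reactions is left to the caller via the shared-`seen`
  mechanism; per-reaction outputs mirror the reaction-split layout of
  published library exports.
- Single-conformer NPR under-samples flexible molecules (above).
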