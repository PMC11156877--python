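# rxnenum

Reaction-based combinatorial enumeration of make-on-demand chemical
libraries, for computational and medicinal chemists who want to build,
filter and profile virtual compound collections from SMARTS-encoded
chemistry and tiered building-block catalogs.

Ultra-large screening libraries are not stored — they are *implied* by a
small set of reliable reactions and the catalog of purchasable reagents
compatible with each one. `rxnenum` implements that workflow end to end:

- **Reaction registry** — parse/validate reaction definitions: synthon
  inclusion/exclusion SMARTS, symmetry filters, reaction tags, and
  atom-mapped transform variants (`reagents ⟶ product` SMARTS). Six
  definitions ship as built-ins: β-keto-imides (with β-keto-acid/ester
  precursor transforms to dioxinones), 5-amino-thiatriazoles,
  5-amino-tetrazoles, the Truce-Smiles rearrangement (12 variants), and
  [2+2]- (4 variants) and [4+2]-cycloadditions (6 variants).
- **Building blocks** — five-tier purchasability model (BB-50 … BB-10,
  "cheap" = BB-50/BB-40), salt stripping, synthon-compatibility filtering
  with synthon-specific and reaction-global exclusion SMARTS, and a
  40-heavy-atom cap.
- **Enumerator** — chunked, deterministic cross-product application of
  every variant with InChIKey dedup, largest-fragment by-product removal,
  provenance (`reaction_variant_reagentA[_reagentB]` IDs) and
  purchasability coding (1 = all BB-50; 2 = cheap with ≥ 1 BB-40), plus a
  MaxMin/ECFP4 diversity sampler for synthesis curation sets.
- **Descriptors** — MW, Crippen cLogP, Lipinski HBA/HBD, rotatable bonds,
  TPSA, Fsp3, QED; a druglike gate (Lipinski + Veber + heavy-atom cap
  ≤ 38: MW ≤ 500, cLogP ≤ 5, HBA ≤ 10, HBD ≤ 5, ROTB ≤ 10, TPSA ≤ 140);
  PAINS A/B/C, Brenk and NIH structural-alert flags and library rates.
- **Diversity** — Bemis-Murcko scaffold census and cross-library overlap;
  principal-moment shape analysis (NPR1 = I1/I3, NPR2 = I2/I3, 200×200
  triangle binning); InChIKey identity search partitioned by heavy-atom
  count and key prefix.
- **IO & fixtures** — readers/writers for tab-delimited SMILES, catalog
  and enumeration-CSV layouts, and a deterministic synthetic
  building-block generator for the fourteen reagent classes the packaged
  reactions consume.

See `docs/methods.md` for the underlying conventions and their rationale.

## Worked example

Enumerate 5-amino-tetrazoles (amine + isothiocyanate) over small synthetic
reagent pools and profile the products:

```python
from rxnenum import builtin, compute_descriptors, enumerate_products, scaffold_census
from rxnenum.io_fixtures import fixture_pools

defn = builtin("amino_tetrazoles")
pools = fixture_pools("amino_tetrazoles", n_per_class=3, seed=7)   # 3 amines x 3 isothiocyanates
products = list(enumerate_products(defn, pools))
print(len(products))
for p in products[:3]:
    rec = compute_descriptors(p.smiles)
    print(p.smiles, p.product_id, p.purchasability,
          f"mw={rec.mw:.1f} qed={rec.qed:.2f} druglike={rec.druglike}")
census = scaffold_census(p.smiles for p in products)
print("scaffolds:", census.n_scaffolds)
```

prints

```
9
CCCn1nnnc1NC1CCCCC1 amino_tetrazoles_V1_FIX-primary_amine-0_FIX-isothiocyanate-0 expensive mw=209.3 qed=0.82 druglike=True
CCc1ccc(-n2nnnc2NC2CCCCC2)cc1 amino_tetrazoles_V1_FIX-primary_amine-0_FIX-isothiocyanate-1 expensive mw=271.4 qed=0.93 druglike=True
c1ccc(Cn2nnnc2NC2CCCCC2)cc1 amino_tetrazoles_V1_FIX-primary_amine-0_FIX-isothiocyanate-2 expensive mw=257.3 qed=0.91 druglike=True
scaffolds: 6
```

Nine products — the full 3 × 3 cross-product, each unique by InChIKey. The
first three come from cyclohexyl isothiocyanate plus three amines; their
product IDs record reaction, variant and reagent provenance. Purchasability
reflects the reagent tiers drawn by the fixture generator (`expensive`
products would be omitted from a cheap export); all pass the druglike gate,
and the nine products spread over six Bemis-Murcko scaffolds.

The same stages are scriptable from the shell:

```bash
rxnenum fixtures --synthon-class primary_amine --n 5 --seed 1 --out amines.smi
rxnenum filter-bb --catalog amines.smi --reaction amino_thiatriazoles --synthon A --out filtered.smi
rxnenum enumerate --reaction amino_tetrazoles --n-per-class 4 --seed 1 \
        --out-smiles tet.smi --out-csv tet.csv
rxnenum diversity --in tet.smi
rxnenum compare --a tet.smi --b other.smi
```

## Reaction definition files

Definitions live in a two-file, tab-separated, line-oriented format
(`#` comments allowed), mirrored by the packaged built-ins under
`src/rxnenum/data/`:

```
# NAME_Reagents.txt
SYNTHON    <id>  <inclusion SMARTS>[|<alternative>...]
EXCLUDE    <id>  <exclusion SMARTS>        # or "*" for reaction-global rules
SYMMETRIC  <id>  <symmetry SMARTS>
PRECURSOR  <id>  <one-component transform> # marks a purchasable precursor class
TAG        <id>  <tag>[,<tag>...]

# NAME_Reactions.txt
REACTION   <variant_id>  <mapped transform SMARTS>  <tag1>[,<tag2>]  [key=value,...]
```

`parse_synthon_file` / `parse_reaction_file` give line-numbered
diagnostics; `validate()` cross-checks tags, arities and atom-map balance;
`serialize()` round-trips.

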