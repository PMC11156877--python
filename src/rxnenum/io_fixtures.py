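"""File formats and the deterministic synthetic building-block generator.

File formats
------------
* SMILES files: one record per line, ``SMILES<TAB>product_name``.
* Product CSV: comma-delimited with a fixed, documented column order
  (:data:`CSV_COLUMNS`); floats serialized to 6 significant digits.
* Catalog files: ``SMILES<TAB>vendor_id<TAB>tier`` (tier token ``BB-50`` ...
  ``BB-10``, dash optional).

Fixture generator
-----------------
:func:`generate_fixtures` emits deterministic synthetic building blocks for
each reagent class the packaged reactions consume (amines, amides,
isothiocyanates, EWG-bearing acyl halides, beta-keto acids, anhydrides,
olefins, furans, pyrroles, cyclopentadienes, aryl Z-H and aryl
sulfonamides). Candidates are assembled from curated sub-fragment grammars
(small alkyl/aryl decorations on each class's core motif), so class
membership is guaranteed by construction; every emitted block is verified
against the consuming reaction's inclusion and global-exclusion SMARTS and
the 40-heavy-atom cap, and generation fails loudly rather than
under-delivering.
"""

from __future__ import annotations

import dataclasses
import itertools
import random
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._chem import ChemistryError
from .building_blocks import BuildingBlock, SynthonMatch, Tier, match_synthon
from .enumerator import EnumeratedProduct
from .reaction_registry import ReactionDefinition, builtin


# ---------------------------------------------------------------------------
# SMILES files


def write_smiles(products: Iterable[EnumeratedProduct | tuple[str, str]],
                 path: str | Path) -> int:
    """Write ``SMILES<TAB>name`` lines; returns the record count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for item in products:
            smiles, name = (item.smiles, item.product_id) \
                if isinstance(item, EnumeratedProduct) else item
            fh.write(f"{smiles}\t{name}\n")
            n += 1
    return n


def read_smiles(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated "
                                 f"fields, got {len(fields)}")
            out.append((fields[0], fields[1]))
    return out


# ---------------------------------------------------------------------------
# product CSV


#: fixed column order of the enumeration CSV
CSV_COLUMNS = ("smiles", "product_id", "reagent_1", "reagent_2",
               "mw", "clogp", "hba", "hbd", "rotb", "tpsa", "hac",
               "fsp3", "qed", "druglike", "purchasability")

_FLOAT_COLUMNS = ("mw", "clogp", "tpsa", "fsp3", "qed")
_INT_COLUMNS = ("hba", "hbd", "rotb", "hac")


@dataclasses.dataclass(frozen=True)
class ProductsCsvRow:
    smiles: str
    product_id: str
    reagent_ids: tuple[str, ...]
    mw: float
    clogp: float
    hba: int
    hbd: int
    rotb: int
    tpsa: float
    hac: int
    fsp3: float
    qed: float
    druglike: bool
    purchasability: int  # 1 or 2 in cheap exports

    def as_record(self) -> dict:
        rec = {"smiles": self.smiles, "product_id": self.product_id,
               "reagent_1": self.reagent_ids[0],
               "reagent_2": self.reagent_ids[1] if len(self.reagent_ids) > 1 else ""}
        for col in _FLOAT_COLUMNS:
            rec[col] = float(f"{getattr(self, col):.6g}")
        for col in _INT_COLUMNS:
            rec[col] = getattr(self, col)
        rec["druglike"] = int(self.druglike)
        rec["purchasability"] = int(self.purchasability)
        return rec


def write_products_csv(rows: Iterable[ProductsCsvRow], path: str | Path,
                       cheap_export: bool = True) -> int:
    """Write the enumeration CSV. In cheap exports (default) the
    purchasability code must be 1 or 2; anything else raises ValueError."""
    records = []
    for row in rows:
        if cheap_export and int(row.purchasability) not in (1, 2):
            raise ValueError(
                f"{row.product_id}: purchasability {int(row.purchasability)} "
                "invalid in a cheap export (must be 1 or 2)")
        records.append(row.as_record())
    frame = pd.DataFrame.from_records(records, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False, float_format="%.6g")
    return len(records)


def read_products_csv(path: str | Path) -> list[ProductsCsvRow]:
    frame = pd.read_csv(path, dtype={"reagent_1": str, "reagent_2": str},
                        keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    rows = []
    for rec in frame.to_dict("records"):
        reagents = (str(rec["reagent_1"]),)
        if str(rec["reagent_2"]):
            reagents += (str(rec["reagent_2"]),)
        rows.append(ProductsCsvRow(
            smiles=rec["smiles"], product_id=rec["product_id"], reagent_ids=reagents,
            mw=float(rec["mw"]), clogp=float(rec["clogp"]), hba=int(rec["hba"]),
            hbd=int(rec["hbd"]), rotb=int(rec["rotb"]), tpsa=float(rec["tpsa"]),
            hac=int(rec["hac"]), fsp3=float(rec["fsp3"]), qed=float(rec["qed"]),
            druglike=bool(int(rec["druglike"])),
            purchasability=int(rec["purchasability"]),
        ))
    return rows


def product_row(product: EnumeratedProduct, hac_cap: int | None = 38) -> ProductsCsvRow:
    """Compute descriptors for an enumerated product and build its CSV row."""
    from .descriptors import compute_descriptors

    rec = compute_descriptors(product.smiles, hac_cap=hac_cap)
    return ProductsCsvRow(
        smiles=product.smiles, product_id=product.product_id,
        reagent_ids=product.reagent_ids, mw=rec.mw, clogp=rec.clogp, hba=rec.hba,
        hbd=rec.hbd, rotb=rec.rotb, tpsa=rec.tpsa, hac=rec.hac, fsp3=rec.fsp3,
        qed=rec.qed, druglike=rec.druglike,
        purchasability=int(product.purchasability),
    )


# ---------------------------------------------------------------------------
# catalogs


def write_catalog(blocks: Iterable[BuildingBlock], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for block in blocks:
            fh.write(f"{block.smiles}\t{block.vendor_id}\t{block.tier.value}\n")
            n += 1
    return n


def read_catalog(path: str | Path) -> list[BuildingBlock]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{line_no}: expected 3 tab-separated "
                                 f"fields, got {len(fields)}")
            smiles, vendor_id, tier_token = fields
            out.append(BuildingBlock.from_smiles(smiles, vendor_id,
                                                 Tier.parse(tier_token)))
    return out


# ---------------------------------------------------------------------------
# fixture generator


#: default tier distribution of generated catalogs (weights)
DEFAULT_TIER_MIX = ((Tier.BB50, 0.40), (Tier.BB40, 0.30), (Tier.BB30, 0.15),
                    (Tier.BB20, 0.10), (Tier.BB10, 0.05))

_ALKYL = ("C", "CC", "CCC", "CC(C)", "CCCC", "CC(C)C", "CCCCC", "C1CCCCC1",
          "CCc1ccccc1", "Cc1ccccc1")
_SMALL_ALKYL = ("C", "CC", "CCC", "CC(C)")
_EWG = ("C#N", "S(C)(=O)=O", "C(C)=O", "C(=O)OC")
_OLEFIN_EWG = ("C(C)=O", "C(=O)OC", "C#N", "c1ccccc1", "c1ccc(C)cc1",
               "C(=O)CC", "c1ccc(OC)cc1", "C(=O)C(C)C")


def _acyl_halides() -> list[str]:
    out = []
    for halide, chain, r2, ewg in itertools.product(
            ("Cl", "Br"), ("", "C", "CC"), ("", "C", "CC"), _EWG):
        center = f"C({r2}){ewg}" if r2 else f"C{ewg}"
        out.append(f"O=C({halide}){chain}{center}")
    return out


def _class_candidates() -> dict[str, list[str]]:
    aryl = ("c1ccccc1", "c1ccc(C)cc1", "c1ccc(OC)cc1", "c1cccc(C)c1",
            "c1ccc(CC)cc1", "c1ccc2ccccc2c1")
    return {
        "primary_amine": [f"N{a}" for a in _ALKYL] + ["NCCCOC", "NCCN(C)C"],
        "secondary_amine": [f"N({a}){b}" for a, b in
                            itertools.product(_SMALL_ALKYL, _ALKYL)],
        "amide": [f"O=C(N){a}" for a in _ALKYL]
                 + [f"O=C(N{b}){a}" for a, b in itertools.product(_ALKYL, _SMALL_ALKYL)],
        "isothiocyanate": [f"S=C=N{a}" for a in _ALKYL]
                          + [f"S=C=N{a}" for a in aryl],
        "acyl_halide_ewg": _acyl_halides(),
        "beta_keto_acid": [f"OC(=O)CC(=O){a}" for a in
                           ("C", "CC", "CCC", "CC(C)", "CC(C)C", "CCCC",
                            "CCCCC", "CC1CCCCC1", "C1CCCCC1", "CCCCCC")],
        "anhydride": [f"O=C({a})OC(=O){b}" for a, b in
                      itertools.product(("C", "CC", "CCC", "CC(C)", "c1ccccc1"),
                                        repeat=2)],
        "olefin_1sub": [f"C=C{e}" for e in _OLEFIN_EWG],
        "olefin_11sub": [f"C=C({m}){e}" for m, e in
                         itertools.product(("C", "CC", "CCC"), _OLEFIN_EWG)],
        "furan": ["c1ccoc1", "Cc1ccco1", "CCc1ccco1", "CCCc1ccco1",
                  "Cc1ccc(C)o1", "CCc1ccc(C)o1", "Cc1ccc(CC)o1", "CC(C)c1ccco1",
                  "Cc1occ(C)c1", "CCCCc1ccco1"],
        "pyrrole": ["Cn1cccc1", "CCn1cccc1", "CCCn1cccc1", "CC(C)n1cccc1",
                    "Cn1cccc1C", "Cn1ccc(C)c1", "CCn1cccc1C", "Cn1c(C)ccc1C",
                    "CCCCn1cccc1", "C1CCCCC1n1cccc1"],
        "cyclopentadiene": ["C1=CC=CC1", "CC1=CC=CC1", "CCC1=CC=CC1",
                            "CC(C)C1=CC=CC1", "CC1=CC=C(C)C1", "CCCC1=CC=CC1",
                            "CC1=CC(C)=CC1", "CCCCC1=CC=CC1",
                            "CCCCCC1=CC=CC1", "c1ccccc1C1=CC=CC1"],
        "aryl_ZH": [f"N{a}" for a in aryl] + [f"O{a}" for a in aryl]
                   + ["Sc1ccccc1", "Sc1ccc(C)cc1", "Nc1ccncc1", "Oc1ccncc1"],
        "aryl_sulfonamide": [f"NS(=O)(=O){a}" for a in aryl]
                            + ["NS(=O)(=O)c1ccncc1", "NS(=O)(=O)c1ccc(F)cc1"],
    }


#: class -> (reaction_id, acceptable synthon_ids) used for verification
CLASS_SYNTHONS = {
    "primary_amine": ("amino_thiatriazoles", ("A",)),
    "secondary_amine": ("amino_thiatriazoles", ("A",)),
    "amide": ("beta_keto_imides", ("B",)),
    "isothiocyanate": ("amino_tetrazoles", ("B",)),
    "acyl_halide_ewg": ("truce_smiles",
                        ("B_H0", "B_H1", "B_H2", "B_R0", "B_R1", "B_R2")),
    "beta_keto_acid": ("beta_keto_imides", ("A_PRE",)),
    "anhydride": ("cycloaddition_2_2", ("A_ANHYDRIDE",)),
    "olefin_1sub": ("cycloaddition_2_2", ("B_MONOSUB",)),
    "olefin_11sub": ("cycloaddition_2_2", ("B_DISUB",)),
    "furan": ("cycloaddition_4_2", ("B_FURAN",)),
    "pyrrole": ("cycloaddition_4_2", ("B_PYRROLE",)),
    "cyclopentadiene": ("cycloaddition_4_2", ("B_CYCLOPENTADIENE",)),
    "aryl_ZH": ("truce_smiles", ("A_ZH",)),
    "aryl_sulfonamide": ("truce_smiles", ("A_SULFONAMIDE",)),
}

SYNTHON_CLASSES = tuple(CLASS_SYNTHONS)

#: extra (reaction_id, synthon_id) slots served by an existing class grammar:
#: tetrazoles share the amine synthon, cycloadditions share reagent A, and
#: simple acyl chlorides are covered by the EWG acyl-halide grammar
EXTRA_SLOT_CLASSES = {
    ("amino_tetrazoles", "A"): "primary_amine",
    ("cycloaddition_2_2", "A_ACYL_CHLORIDE"): "acyl_halide_ewg",
    ("cycloaddition_4_2", "A_ANHYDRIDE"): "anhydride",
    ("cycloaddition_4_2", "A_ACYL_CHLORIDE"): "acyl_halide_ewg",
}


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    synthon_class: str
    n: int
    seed: int = 0
    tier_mix: tuple[tuple[Tier, float], ...] = DEFAULT_TIER_MIX

    def __post_init__(self) -> None:
        if self.synthon_class not in CLASS_SYNTHONS:
            raise ValueError(f"unknown synthon class {self.synthon_class!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")


def _accepts(smiles: str, reaction: ReactionDefinition,
             synthon_ids: Sequence[str]) -> bool:
    try:
        block = BuildingBlock.from_smiles(smiles, "tmp", Tier.BB50)
    except ChemistryError:
        return False
    return any(
        match_synthon(block, reaction.synthon(sid), reaction.global_exclusions)
        is not None
        for sid in synthon_ids)


def generate_fixtures(spec: FixtureSpec) -> list[BuildingBlock]:
    """Deterministic synthetic blocks of one reagent class.

    Every returned block matches an inclusion pattern of its class's synthon
    under the consuming reaction's global exclusions and the 40-heavy-atom
    cap. Vendor IDs follow ``FIX-<class>-<index>``; tiers are drawn from the
    spec's tier mix with the spec's seed. Raises ValueError when the grammar
    cannot supply ``n`` distinct valid molecules.
    """
    if spec.n == 0:
        return []
    reaction_id, synthon_ids = CLASS_SYNTHONS[spec.synthon_class]
    reaction = builtin(reaction_id)
    candidates = list(dict.fromkeys(_class_candidates()[spec.synthon_class]))
    rng = random.Random(spec.seed)
    rng.shuffle(candidates)

    tiers, weights = zip(*spec.tier_mix)
    chosen: list[str] = []
    for smiles in candidates:
        if _accepts(smiles, reaction, synthon_ids):
            chosen.append(smiles)
            if len(chosen) == spec.n:
                break
    if len(chosen) < spec.n:
        raise ValueError(
            f"class {spec.synthon_class!r}: only {len(chosen)} of {spec.n} "
            "requested fixtures satisfy the class constraints")
    return [
        BuildingBlock.from_smiles(
            smiles, f"FIX-{spec.synthon_class}-{i}", rng.choices(tiers, weights)[0])
        for i, smiles in enumerate(chosen)
    ]


def generate_decoys(reaction_id: str, synthon_id: str, n: int,
                    seed: int = 0) -> list[BuildingBlock]:
    """Blocks *rejected* by a synthon (drawn from other classes and inert
    molecules), for exercising the negative side of catalog filtering."""
    inert = ["CCCCCC", "c1ccccc1", "CCOCC", "CC(C)OC(C)C", "CCCCOCC",
             "c1ccc2ccccc2c1", "C1CCOCC1", "CC(C)(C)C", "CCCCCCCC", "COc1ccccc1"]
    pool = inert + [s for cands in _class_candidates().values() for s in cands]
    pool = list(dict.fromkeys(pool))
    rng = random.Random(seed)
    rng.shuffle(pool)
    reaction = builtin(reaction_id)
    synthon = reaction.synthon(synthon_id)
    out = []
    for i, smiles in enumerate(pool):
        try:
            block = BuildingBlock.from_smiles(smiles, f"DEC-{synthon_id}-{i}", Tier.BB50)
        except ChemistryError:
            continue
        if match_synthon(block, synthon, reaction.global_exclusions) is None:
            out.append(block)
            if len(out) == n:
                break
    if len(out) < n:
        raise ValueError(f"only {len(out)} of {n} requested decoys found")
    return out


def fixture_pools(reaction_id: str, n_per_class: int = 6,
                  seed: int = 0) -> dict[str, list[SynthonMatch]]:
    """Filtered fixture pools for every synthon of a packaged reaction,
    keyed by synthon_id — the shape :func:`rxnenum.enumerator.enumerate_products`
    consumes."""
    from .building_blocks import filter_catalog

    reaction = builtin(reaction_id)
    class_for_synthon: dict[str, str] = {}
    for cls, (rid, sids) in CLASS_SYNTHONS.items():
        if rid == reaction_id:
            for sid in sids:
                # first class wins (acyl_halide_ewg covers all six TS B slots)
                class_for_synthon.setdefault(sid, cls)
    for (rid, sid), cls in EXTRA_SLOT_CLASSES.items():
        if rid == reaction_id:
            class_for_synthon.setdefault(sid, cls)

    # one full batch per class so vendor IDs are consistent across slots and
    # every condition subclass (chain length, halide, hindrance) is present;
    # each slot's pool is then truncated to n_per_class
    batch: dict[str, list[BuildingBlock]] = {}
    for cls in set(class_for_synthon.values()):
        rid, sids = CLASS_SYNTHONS[cls]
        src = builtin(rid)
        candidates = list(dict.fromkeys(_class_candidates()[cls]))
        n_all = sum(_accepts(s, src, sids) for s in candidates)
        batch[cls] = generate_fixtures(FixtureSpec(cls, n_all, seed))

    pools: dict[str, list[SynthonMatch]] = {}
    for syn in reaction.synthons:
        cls = class_for_synthon.get(syn.synthon_id)
        if cls is None:
            continue
        pools[syn.synthon_id] = filter_catalog(
            batch[cls], syn, reaction.global_exclusions)[:n_per_class]
    return pools
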