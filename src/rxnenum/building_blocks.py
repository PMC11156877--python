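"""Building-block catalogs: purchasability tiers and synthon-compatible filtering.

Commercial catalogs tier building blocks by price and availability, from
BB-50 (in-stock, best price/delivery) down to BB-10 (expensive or
make-on-demand). The *cheap* category is BB-50 plus BB-40; everything else
is *expensive*. Reagent selection applies, in order: salt stripping (largest
organic fragment), inclusion SMARTS (any-of), synthon-specific exclusions,
reaction-global exclusions, and a heavy-atom cap (default 40, applied after
salt stripping).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from typing import Iterable, Sequence

from rdkit import Chem

from ._chem import (ChemistryError, largest_organic_fragment, mol_from_smiles,
                    reaction_from_smarts, smarts_query, with_explicit_hs)
from .reaction_registry import SynthonDefinition

logger = logging.getLogger(__name__)


class Tier(enum.Enum):
    """Availability/price tier, BB50 cheapest-in-stock to BB10 most expensive."""

    BB50 = "BB-50"
    BB40 = "BB-40"
    BB30 = "BB-30"
    BB20 = "BB-20"
    BB10 = "BB-10"

    @classmethod
    def parse(cls, token: str) -> "Tier":
        normalized = token.strip().upper().replace("-", "")
        for tier in cls:
            if tier.name == normalized:
                return tier
        raise ValueError(f"unknown tier token {token!r}")

    @property
    def rank(self) -> int:
        """Price rank; lower is cheaper (BB50 -> 0)."""
        return list(Tier).index(self)


#: tiers making up the "cheap" category
CHEAP_TIERS = frozenset({Tier.BB50, Tier.BB40})


def classify_cheap(tier: Tier) -> bool:
    """True iff the tier belongs to the cheap category (BB-50 or BB-40)."""
    return tier in CHEAP_TIERS


@dataclasses.dataclass(frozen=True)
class BuildingBlock:
    """A catalog entry after standardization (salt-stripped, canonical)."""

    smiles: str
    vendor_id: str
    tier: Tier
    heavy_atoms: int
    salt_stripped: bool = False

    @classmethod
    def from_smiles(cls, smiles: str, vendor_id: str, tier: Tier) -> "BuildingBlock":
        mol = mol_from_smiles(smiles)
        mol, stripped = largest_organic_fragment(mol)
        return cls(
            smiles=Chem.MolToSmiles(mol),
            vendor_id=vendor_id,
            tier=tier,
            heavy_atoms=mol.GetNumHeavyAtoms(),
            salt_stripped=stripped,
        )

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


@dataclasses.dataclass(frozen=True)
class SynthonMatch:
    """A block accepted for a synthon, with every distinct embedding site."""

    block: BuildingBlock
    synthon_id: str
    match_sites: tuple[tuple[int, ...], ...]
    symmetric: bool = False


def dedup_blocks(blocks: Iterable[BuildingBlock]) -> list[BuildingBlock]:
    """Drop repeated vendor IDs, keeping the cheapest tier seen for each."""
    best: dict[str, BuildingBlock] = {}
    order: list[str] = []
    for block in blocks:
        prev = best.get(block.vendor_id)
        if prev is None:
            best[block.vendor_id] = block
            order.append(block.vendor_id)
        elif block.tier.rank < prev.tier.rank:
            best[block.vendor_id] = block
    return [best[vid] for vid in order]


def _heavy_sites(mol_h: Chem.Mol, query: Chem.Mol) -> list[tuple[int, ...]]:
    """Distinct embeddings of ``query``, reported as heavy-atom index tuples.

    Matching runs on an explicit-hydrogen copy so patterns with literal [H]
    atoms behave; hydrogens are dropped from the reported sites. AddHs
    appends hydrogens after the heavy atoms, so heavy indices are unchanged.
    """
    n_heavy = sum(1 for a in mol_h.GetAtoms() if a.GetAtomicNum() > 1)
    sites = []
    for match in mol_h.GetSubstructMatches(query, uniquify=True):
        heavy = tuple(i for i in match if i < n_heavy)
        if heavy and heavy not in sites:
            sites.append(heavy)
    return sites


def match_synthon(block: BuildingBlock, synthon: SynthonDefinition,
                  global_exclusions: Sequence[str] = (),
                  max_heavy_atoms: int = 40) -> SynthonMatch | None:
    """Test one block against one synthon; None when any rule rejects it."""
    if block.heavy_atoms > max_heavy_atoms:
        return None
    mol_h = with_explicit_hs(block.mol())

    sites: list[tuple[int, ...]] = []
    for pattern in synthon.inclusion_patterns:
        for site in _heavy_sites(mol_h, smarts_query(pattern)):
            if site not in sites:
                sites.append(site)
    if not sites:
        return None

    for pattern in synthon.exclusion_patterns:
        if mol_h.HasSubstructMatch(smarts_query(pattern)):
            return None
    for pattern in global_exclusions:
        if mol_h.HasSubstructMatch(smarts_query(pattern)):
            return None

    symmetric = bool(
        synthon.symmetric_pattern
        and mol_h.HasSubstructMatch(smarts_query(synthon.symmetric_pattern))
    )
    return SynthonMatch(block=block, synthon_id=synthon.synthon_id,
                        match_sites=tuple(sites), symmetric=symmetric)


def filter_catalog(blocks: Iterable[BuildingBlock | str] | Iterable,
                   synthon: SynthonDefinition,
                   global_exclusions: Sequence[str] = (),
                   max_heavy_atoms: int = 40) -> list[SynthonMatch]:
    """Select catalog entries compatible with a synthon.

    A block is accepted iff it matches at least one inclusion pattern, no
    synthon-specific exclusion, no reaction-global exclusion, and is at most
    ``max_heavy_atoms`` heavy atoms. Input order is preserved; unparseable
    SMILES are logged and skipped, never fatal.
    """
    out = []
    for i, block in enumerate(blocks):
        if isinstance(block, str):
            try:
                block = BuildingBlock.from_smiles(block, vendor_id=f"BB-{i}", tier=Tier.BB50)
            except ChemistryError as exc:
                logger.warning("skipping unparseable block: %s", exc)
                continue
        match = match_synthon(block, synthon, global_exclusions, max_heavy_atoms)
        if match is not None:
            out.append(match)
    return out


def apply_precursor(block: BuildingBlock | str, precursor: SynthonDefinition,
                    transform: str | None = None) -> list[str]:
    """Convert a purchasable precursor into the reactive reagent class.

    Runs the synthon's one-component precursor transform(s) (or an explicit
    ``transform``) over every embedding and returns the distinct canonical
    products, sorted. Empty when no transform applies.
    """
    smiles = block.smiles if isinstance(block, BuildingBlock) else block
    mol = mol_from_smiles(smiles)
    transforms = (transform,) if transform is not None else precursor.precursor_transforms
    products: set[str] = set()
    for tf in transforms:
        rxn = reaction_from_smarts(tf)
        for reactant in (mol, with_explicit_hs(mol)):
            try:
                results = rxn.RunReactants((reactant,))
            except Exception:  # pragma: no cover - defensive
                continue
            for tup in results:
                for product in tup:
                    try:
                        Chem.SanitizeMol(product)
                        product = Chem.RemoveHs(product)
                    except Exception:
                        continue
                    products.add(Chem.MolToSmiles(product))
    return sorted(products)
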