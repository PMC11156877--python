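"""Combinatorial product enumeration with provenance and purchasability.

Products are generated by applying each transform variant of a reaction
definition over the cross-product of its filtered reagent pools, in chunks
of up to ``chunk_size`` first-slot reagents (the unit the original
large-scale runs distributed over worker processes). Results are a pure
function of (definition, pools, options): any chunking or partitioning
reproduces the single-pass product set.

Transforms are run twice per reagent tuple, once on the plain molecules and
once on explicit-hydrogen copies, and the results merged. Atom-mapped
hydrogens (``[H:n]``) and wildcards that must bind a hydrogen only match
explicit-H molecules, while transforms written against implicit-H molecules
can produce valence errors when hydrogens are explicit; invalid raw products
are dropped. Each raw product keeps only its largest fragment (ties broken
by smallest canonical SMILES), discarding leaving-group by-products such as
the acetonide fragment of the beta-keto-imide condensation. Uniqueness is
keyed on the standard InChIKey.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Iterable, Iterator, Sequence

from rdkit import Chem

from ._chem import mol_from_smiles, reaction_from_smarts, with_explicit_hs
from .building_blocks import SynthonMatch, Tier, classify_cheap
from .reaction_registry import ReactionDefinition, ReactionVariant


class Purchasability(enum.IntEnum):
    """Cost coding of a product from its reagent tiers.

    CODE_1: every reagent is BB-50.
    CODE_2: every reagent is cheap (BB-50/BB-40) with at least one BB-40.
    EXPENSIVE: at least one reagent outside the cheap category.
    """

    CODE_1 = 1
    CODE_2 = 2
    EXPENSIVE = 3

    def __str__(self) -> str:  # CSV-friendly
        return "expensive" if self is Purchasability.EXPENSIVE else str(self.value)


def assign_purchasability(reagent_tiers: Sequence[Tier]) -> Purchasability:
    if not reagent_tiers:
        raise ValueError("empty reagent tier list")
    if all(t is Tier.BB50 for t in reagent_tiers):
        return Purchasability.CODE_1
    if all(classify_cheap(t) for t in reagent_tiers):
        return Purchasability.CODE_2
    return Purchasability.EXPENSIVE


@dataclasses.dataclass(frozen=True)
class EnumeratedProduct:
    smiles: str
    product_id: str
    inchikey: str
    reaction_id: str
    variant_id: str
    reagent_ids: tuple[str, ...]
    purchasability: Purchasability


@dataclasses.dataclass
class EnumerationOptions:
    chunk_size: int = 2000
    dedup_scope: str = "per_reaction"  # or "global"
    max_products: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.dedup_scope not in ("per_reaction", "global"):
            raise ValueError(f"unknown dedup_scope {self.dedup_scope!r}")


def _best_fragment(product: Chem.Mol) -> str | None:
    """Canonical SMILES of the largest sanitizable fragment, else None."""
    try:
        Chem.SanitizeMol(product)
        product = Chem.RemoveHs(product)
    except Exception:
        return None
    best: tuple[int, str] | None = None
    for frag in Chem.GetMolFrags(product, asMols=True, sanitizeFrags=False):
        smi = Chem.MolToSmiles(frag)
        ha = frag.GetNumHeavyAtoms()
        if best is None or ha > best[0] or (ha == best[0] and smi < best[1]):
            best = (ha, smi)
    return best[1] if best else None


def apply_variant(variant: ReactionVariant | str,
                  reagents: Sequence[Chem.Mol | str]) -> list[str]:
    """All distinct canonical products of one transform on one reagent tuple.

    Accepts a :class:`ReactionVariant` or a bare transform SMARTS, and
    molecules or SMILES. Returns a sorted list; empty when the transform does
    not apply. Raw products that fail sanitization are dropped.
    """
    transform = variant if isinstance(variant, str) else variant.transform
    rxn = reaction_from_smarts(transform)
    mols = [mol_from_smiles(r) if isinstance(r, str) else r for r in reagents]
    if len(mols) != rxn.GetNumReactantTemplates():
        raise ValueError(
            f"variant arity {rxn.GetNumReactantTemplates()} != {len(mols)} reagents")

    products: set[str] = set()
    for add_hs in (False, True):
        inputs = tuple(with_explicit_hs(m) if add_hs else m for m in mols)
        try:
            results = rxn.RunReactants(inputs)
        except Exception:  # pragma: no cover - defensive
            continue
        # a product tuple may contain by-products ('.'-separated product side);
        # keep only the largest fragment over the whole tuple
        for tup in results:
            best: tuple[int, str] | None = None
            for raw in tup:
                smi = _best_fragment(raw)
                if smi is None:
                    continue
                ha = mol_from_smiles(smi).GetNumHeavyAtoms()
                if best is None or ha > best[0] or (ha == best[0] and smi < best[1]):
                    best = (ha, smi)
            if best is not None:
                products.add(best[1])
    return sorted(products)


@dataclasses.dataclass(frozen=True)
class _PoolEntry:
    smiles: str
    vendor_id: str
    tier: Tier


def _slot_pool(defn: ReactionDefinition, tag: str,
               pools: dict[str, list[SynthonMatch]],
               tiers: dict[str, Tier] | None) -> list[_PoolEntry]:
    """Reagents feeding one component slot: direct matches of the slot's
    synthon plus the expanded products of any precursor synthon sharing the
    slot's tag (each derived reagent inherits vendor ID and tier)."""
    from .building_blocks import apply_precursor

    def tier_of(match: SynthonMatch) -> Tier:
        if tiers is not None and match.block.vendor_id in tiers:
            return tiers[match.block.vendor_id]
        return match.block.tier

    entries: list[_PoolEntry] = []
    synthon = defn.resolve_tag(tag)
    for match in pools.get(synthon.synthon_id, []):
        entries.append(_PoolEntry(match.block.smiles, match.block.vendor_id, tier_of(match)))
    for precursor in defn.precursors_for_tag(tag):
        for match in pools.get(precursor.synthon_id, []):
            derived = apply_precursor(match.block, precursor)
            for j, smi in enumerate(derived):
                vid = match.block.vendor_id if len(derived) == 1 \
                    else f"{match.block.vendor_id}.{j + 1}"
                entries.append(_PoolEntry(smi, vid, tier_of(match)))
    return entries


def _chunks(seq: list, size: int) -> Iterator[list]:
    for i in range(0, len(seq), size):
        yield seq[i:i + size]


def enumerate_products(defn: ReactionDefinition,
                       pools: dict[str, list[SynthonMatch]],
                       tiers: dict[str, Tier] | None = None,
                       opts: EnumerationOptions | None = None,
                       seen: set[str] | None = None) -> Iterator[EnumeratedProduct]:
    """Stream unique products of every variant over the reagent pools.

    ``pools`` maps synthon_id to the :class:`SynthonMatch` lists produced by
    catalog filtering; precursor synthons are expanded on the fly. ``tiers``
    optionally overrides per-vendor tiers. Each product is yielded exactly
    once within the dedup scope, keyed on InChIKey; pass a shared ``seen``
    set to dedup across calls (``dedup_scope="global"``).
    """
    opts = opts or EnumerationOptions()
    if seen is None:
        seen = set()
    emitted = 0

    for variant in defn.variants:
        slot_pools = [_slot_pool(defn, tag, pools, tiers) for tag in variant.component_tags]
        if any(not pool for pool in slot_pools):
            empty = [tag for tag, pool in zip(variant.component_tags, slot_pools) if not pool]
            warnings.warn(
                f"{defn.reaction_id}/{variant.variant_id}: empty pool for {empty}",
                stacklevel=2)
            continue

        mol_cache = {e.smiles: mol_from_smiles(e.smiles)
                     for pool in slot_pools for e in pool}

        def emit(entries: tuple[_PoolEntry, ...]) -> Iterator[EnumeratedProduct]:
            for smi in apply_variant(variant, [mol_cache[e.smiles] for e in entries]):
                inchikey = Chem.MolToInchiKey(mol_from_smiles(smi))
                if not inchikey or inchikey in seen:
                    continue
                seen.add(inchikey)
                yield EnumeratedProduct(
                    smiles=smi,
                    product_id="_".join([defn.reaction_id, variant.variant_id,
                                         *(e.vendor_id for e in entries)]),
                    inchikey=inchikey,
                    reaction_id=defn.reaction_id,
                    variant_id=variant.variant_id,
                    reagent_ids=tuple(e.vendor_id for e in entries),
                    purchasability=assign_purchasability([e.tier for e in entries]),
                )

        if len(slot_pools) == 1:
            combos: Iterable[tuple[_PoolEntry, ...]] = (
                (a,) for chunk in _chunks(slot_pools[0], opts.chunk_size) for a in chunk)
        else:
            combos = ((a, b)
                      for chunk in _chunks(slot_pools[0], opts.chunk_size)
                      for a in chunk for b in slot_pools[1])

        for combo in combos:
            for product in emit(combo):
                yield product
                emitted += 1
                if opts.max_products is not None and emitted >= opts.max_products:
                    return


def curation_sample(products: Sequence[EnumeratedProduct | str], k: int,
                    seed: int = 0) -> list:
    """Diversity pick of ``k`` products by the MaxMin algorithm over
    2048-bit radius-2 circular (ECFP4-like) fingerprints with Tanimoto
    distance. Deterministic for a fixed seed. If ``k`` exceeds the input
    size, returns everything with a warning.
    """
    from rdkit.Chem import rdFingerprintGenerator
    from rdkit.SimDivFilters.rdSimDivPickers import MaxMinPicker

    items = list(products)
    if k >= len(items):
        if k > len(items):
            warnings.warn(f"requested {k} > {len(items)} products; returning all",
                          stacklevel=2)
        return items
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    fps = [gen.GetFingerprint(mol_from_smiles(
        p.smiles if isinstance(p, EnumeratedProduct) else p)) for p in items]
    picker = MaxMinPicker()
    picks = picker.LazyBitVectorPick(fps, len(fps), k, seed=seed)
    return [items[i] for i in picks]
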