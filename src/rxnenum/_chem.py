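"""Small shared RDKit helpers used across modules."""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

# RDKit is chatty about sanitization failures that this package handles
# explicitly (dropped products, skipped blocks).
RDLogger.DisableLog("rdApp.*")


class ChemistryError(ValueError):
    """A SMILES/SMARTS string could not be interpreted."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


@lru_cache(maxsize=4096)
def smarts_query(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ChemistryError(f"unparseable SMARTS: {pattern!r}")
    return query


@lru_cache(maxsize=512)
def reaction_from_smarts(transform: str) -> AllChem.ChemicalReaction:
    try:
        rxn = AllChem.ReactionFromSmarts(transform)
    except Exception as exc:  # RDKit raises RuntimeError on bad transforms
        raise ChemistryError(f"unparseable reaction SMARTS: {transform!r} ({exc})") from None
    if rxn is None:
        raise ChemistryError(f"unparseable reaction SMARTS: {transform!r}")
    return rxn


def with_explicit_hs(mol: Chem.Mol) -> Chem.Mol:
    """Copy with explicit hydrogens; patterns with literal [H] atoms need them."""
    return Chem.AddHs(mol)


def largest_organic_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Strip salts/solvates: keep the fragment with the most heavy atoms,
    preferring carbon-containing fragments. Returns (fragment, was_stripped).

    Ties are broken by canonical SMILES so the choice is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol, False

    def sort_key(frag: Chem.Mol):
        has_carbon = any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())
        # prefer organic, then largest; break ties on smallest canonical SMILES
        return (-int(has_carbon), -frag.GetNumHeavyAtoms(), Chem.MolToSmiles(frag))

    best = sorted(frags, key=sort_key)[0]
    return best, True
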