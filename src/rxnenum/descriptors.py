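"""Physicochemical descriptors, druglikeness gating and structural alerts.

The druglike gate combines Lipinski's rule of five with Veber's criteria and
a heavy-atom cap: MW <= 500 Da, cLogP <= 5 (Crippen atom-contribution
estimate), HBA <= 10 and HBD <= 5 (Lipinski N/O counting conventions),
rotatable bonds <= 10, TPSA <= 140 A^2, and at most 38 heavy atoms. The
heavy-atom cap is configurable (pass ``hac_cap=None`` to disable) but on by
default. Alert flags come from the published PAINS (A/B/C), Brenk and NIH
substructure catalogs as curated by RDKit's FilterCatalog.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Iterable

from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from ._chem import mol_from_smiles

#: gate cutoffs (upper bounds, inclusive)
MW_MAX = 500.0
CLOGP_MAX = 5.0
HBA_MAX = 10
HBD_MAX = 5
ROTB_MAX = 10
TPSA_MAX = 140.0
HAC_MAX = 38


@dataclasses.dataclass(frozen=True)
class DescriptorRecord:
    mw: float          # molecular weight, Da
    clogp: float       # Crippen logP estimate
    hba: int           # H-bond acceptors (Lipinski N+O count)
    hbd: int           # H-bond donors (Lipinski NH+OH count)
    rotb: int          # rotatable bonds
    tpsa: float        # topological polar surface area, A^2
    hac: int           # heavy atom count
    fsp3: float        # fraction of sp3 carbons
    qed: float         # quantitative estimate of druglikeness
    druglike: bool


@dataclasses.dataclass(frozen=True)
class AlertFlags:
    pains_a: bool
    pains_b: bool
    pains_c: bool
    brenk: bool
    nih: bool

    @property
    def pains(self) -> bool:
        return self.pains_a or self.pains_b or self.pains_c


def druglike_gate(rec: DescriptorRecord, hac_cap: int | None = HAC_MAX) -> bool:
    """Lipinski + Veber verdict; monotone non-increasing in every field."""
    ok = (rec.mw <= MW_MAX and rec.clogp <= CLOGP_MAX and rec.hba <= HBA_MAX
          and rec.hbd <= HBD_MAX and rec.rotb <= ROTB_MAX and rec.tpsa <= TPSA_MAX)
    if hac_cap is not None:
        ok = ok and rec.hac <= hac_cap
    return ok


def compute_descriptors(smiles: str, hac_cap: int | None = HAC_MAX) -> DescriptorRecord:
    """Full descriptor record for one molecule; deterministic, parse errors raise.

    The molecule is canonicalized first so the record is a pure function of
    the structure (atom ordering in the input SMILES cannot perturb
    floating-point summation order).
    """
    from ._chem import canonical_smiles

    mol = mol_from_smiles(canonical_smiles(smiles))
    partial = dict(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        hba=Descriptors.NOCount(mol),
        hbd=Descriptors.NHOHCount(mol),
        rotb=Descriptors.NumRotatableBonds(mol),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        hac=mol.GetNumHeavyAtoms(),
        fsp3=rdMolDescriptors.CalcFractionCSP3(mol),
        qed=QED.qed(mol),
    )
    probe = DescriptorRecord(druglike=False, **partial)
    return dataclasses.replace(probe, druglike=druglike_gate(probe, hac_cap))


_CATALOG_KEYS = {
    "pains_a": FilterCatalogParams.FilterCatalogs.PAINS_A,
    "pains_b": FilterCatalogParams.FilterCatalogs.PAINS_B,
    "pains_c": FilterCatalogParams.FilterCatalogs.PAINS_C,
    "brenk": FilterCatalogParams.FilterCatalogs.BRENK,
    "nih": FilterCatalogParams.FilterCatalogs.NIH,
}


@lru_cache(maxsize=None)
def _catalog(name: str) -> FilterCatalog:
    params = FilterCatalogParams()
    params.AddCatalog(_CATALOG_KEYS[name])
    return FilterCatalog(params)


def structural_alerts(smiles: str) -> AlertFlags:
    """Per-catalog hit flags (true iff >=1 pattern of that catalog matches)."""
    mol = mol_from_smiles(smiles)
    return AlertFlags(**{name: _catalog(name).HasMatch(mol) for name in _CATALOG_KEYS})


def alert_rates(library: Iterable[str | AlertFlags]) -> dict:
    """Fraction of a library flagged by each catalog.

    Accepts SMILES or precomputed :class:`AlertFlags`. Returns
    ``{catalog: {"count": int, "fraction": float}, ..., "n": int}``; an
    aggregate ``pains`` entry (any of A/B/C) is included.
    """
    counts = {name: 0 for name in _CATALOG_KEYS}
    counts["pains"] = 0
    n = 0
    for item in library:
        flags = structural_alerts(item) if isinstance(item, str) else item
        n += 1
        for name in _CATALOG_KEYS:
            counts[name] += int(getattr(flags, name))
        counts["pains"] += int(flags.pains)
    if n == 0:
        raise ValueError("empty library stream")
    out: dict = {name: {"count": c, "fraction": c / n} for name, c in counts.items()}
    out["n"] = n
    return out
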