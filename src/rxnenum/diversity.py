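"""Diversity analytics: scaffolds, 3D shape (PMI/NPR) and identity search.

Scaffold diversity uses Bemis-Murcko frameworks (ring systems plus linkers,
side chains removed); acyclic molecules fall under an empty-scaffold
sentinel counted separately. Shape places each molecule in the rod-disc-
sphere triangle via the normalized principal-moment ratios NPR1 = I1/I3 and
NPR2 = I2/I3 of a single seeded distance-geometry conformer, binned on a
200 x 200 grid over NPR1 in [0, 1] x NPR2 in [0.5, 1]. Identity search
between libraries partitions standard InChIKeys by heavy-atom count and
two-letter key prefix, mirroring a directories-and-files layout that makes
membership lookups cheap at scale.
"""

from __future__ import annotations

import bisect
import dataclasses
import re
import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Scaffolds import MurckoScaffold

from ._chem import mol_from_smiles

#: sentinel scaffold for acyclic molecules (Bemis-Murcko needs a ring)
EMPTY_SCAFFOLD = ""

_TRIANGLE_TOL = 1e-6
_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class EmbeddingError(RuntimeError):
    """3D embedding failed for a molecule."""


# ---------------------------------------------------------------------------
# scaffolds


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES ('' for acyclic molecules)."""
    mol = mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(scaffold)


@dataclasses.dataclass(frozen=True)
class ScaffoldSummary:
    n_compounds: int
    n_scaffolds: int
    scaffold_counts: Mapping[str, int]
    n_acyclic: int = 0

    @property
    def compounds_per_scaffold(self) -> float:
        return self.n_compounds / self.n_scaffolds if self.n_scaffolds else float("nan")


def scaffold_census(smiles_iter: Iterable[str]) -> ScaffoldSummary:
    """Count compounds per Bemis-Murcko scaffold over a library stream.

    Acyclic molecules are tallied under the empty-scaffold sentinel and
    excluded from the scaffold count (but included in ``n_compounds``).
    """
    counts: Counter[str] = Counter()
    n = 0
    for smi in smiles_iter:
        counts[murcko_scaffold(smi)] += 1
        n += 1
    n_acyclic = counts.get(EMPTY_SCAFFOLD, 0)
    n_ring_scaffolds = len(counts) - (1 if EMPTY_SCAFFOLD in counts else 0)
    return ScaffoldSummary(n_compounds=n, n_scaffolds=n_ring_scaffolds,
                           scaffold_counts=dict(counts), n_acyclic=n_acyclic)


@dataclasses.dataclass(frozen=True)
class OverlapResult:
    shared: int
    fraction_a: float
    fraction_b: float


def scaffold_overlap(a: ScaffoldSummary, b: ScaffoldSummary) -> OverlapResult:
    """Shared ring-scaffold count and the fraction of each side it represents."""
    keys_a = set(a.scaffold_counts) - {EMPTY_SCAFFOLD}
    keys_b = set(b.scaffold_counts) - {EMPTY_SCAFFOLD}
    shared = len(keys_a & keys_b)
    return OverlapResult(
        shared=shared,
        fraction_a=shared / len(keys_a) if keys_a else 0.0,
        fraction_b=shared / len(keys_b) if keys_b else 0.0,
    )


# ---------------------------------------------------------------------------
# 3D shape


def principal_moments(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Sorted principal moments of inertia I1 <= I2 <= I3 of a point set."""
    coords = np.asarray(coords, dtype=float)
    masses = np.ones(len(coords)) if masses is None else np.asarray(masses, dtype=float)
    center = np.average(coords, axis=0, weights=masses)
    r = coords - center
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    tensor = np.array([
        [np.sum(masses * (y * y + z * z)), -np.sum(masses * x * y), -np.sum(masses * x * z)],
        [-np.sum(masses * x * y), np.sum(masses * (x * x + z * z)), -np.sum(masses * y * z)],
        [-np.sum(masses * x * z), -np.sum(masses * y * z), np.sum(masses * (x * x + y * y))],
    ])
    return np.sort(np.linalg.eigvalsh(tensor))


def npr_from_points(coords: np.ndarray, masses: np.ndarray | None = None) -> tuple[float, float]:
    """(NPR1, NPR2) = (I1/I3, I2/I3) for an arbitrary mass distribution."""
    i1, i2, i3 = principal_moments(coords, masses)
    if i3 <= 0:
        raise ValueError("degenerate (collapsed) mass distribution")
    return float(i1 / i3), float(i2 / i3)


def npr_shape(smiles: str, seed: int = 42) -> tuple[float, float]:
    """Normalized PMI ratios from one seeded distance-geometry conformer.

    Embeds an explicit-hydrogen copy with the given random seed and computes
    the mass-weighted principal moments of the resulting coordinates.
    Raises :class:`EmbeddingError` when no conformer can be generated.
    """
    mol = Chem.AddHs(mol_from_smiles(smiles))
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        if AllChem.EmbedMolecule(mol, randomSeed=seed, useRandomCoords=True) != 0:
            raise EmbeddingError(f"could not embed {smiles!r}")
    coords = mol.GetConformer().GetPositions()
    masses = np.array([a.GetMass() for a in mol.GetAtoms()])
    return npr_from_points(coords, masses)


@dataclasses.dataclass(frozen=True)
class ShapeGrid:
    nbins: int
    grid: np.ndarray       # (nbins, nbins) counts; rows NPR1, cols NPR2
    n_total: int
    npr1_edges: np.ndarray
    npr2_edges: np.ndarray


def bin_shapes(points: Sequence[tuple[float, float]], nbins: int = 200) -> ShapeGrid:
    """Histogram (NPR1, NPR2) pairs on an nbins x nbins grid over
    [0, 1] x [0.5, 1]. Points outside the shape triangle by more than a
    small tolerance are clamped onto it with a warning.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n_clamped = 0
    if len(pts):
        bad = ((pts[:, 0] < -_TRIANGLE_TOL) | (pts[:, 1] > 1 + _TRIANGLE_TOL)
               | (pts[:, 0] > pts[:, 1] + _TRIANGLE_TOL)
               | (pts[:, 0] + pts[:, 1] < 1 - _TRIANGLE_TOL))
        n_clamped = int(bad.sum())
        if n_clamped:
            warnings.warn(f"{n_clamped} points outside the NPR triangle; clamped",
                          stacklevel=2)
        pts[:, 0] = np.clip(pts[:, 0], 0.0, 1.0)
        pts[:, 1] = np.clip(pts[:, 1], 0.5, 1.0)
        pts[:, 0] = np.minimum(pts[:, 0], pts[:, 1])
        lo = 1.0 - pts[:, 1]
        pts[:, 0] = np.maximum(pts[:, 0], lo)
    grid, e1, e2 = np.histogram2d(pts[:, 0], pts[:, 1], bins=nbins,
                                  range=[[0.0, 1.0], [0.5, 1.0]])
    return ShapeGrid(nbins=nbins, grid=grid, n_total=len(pts),
                     npr1_edges=e1, npr2_edges=e2)


# ---------------------------------------------------------------------------
# InChIKey partitioning


@dataclasses.dataclass(frozen=True, order=True)
class PartitionKey:
    heavy_atoms: int
    prefix: str  # first two (uppercase) letters of the InChIKey

    def __post_init__(self) -> None:
        if len(self.prefix) != 2 or not self.prefix.isupper():
            raise ValueError(f"bad partition prefix {self.prefix!r}")


def _check_key(inchikey: str) -> None:
    if not _INCHIKEY_RE.match(inchikey):
        raise ValueError(f"malformed InChIKey {inchikey!r}")


def partition_key(inchikey: str, heavy_atoms: int) -> PartitionKey:
    _check_key(inchikey)
    return PartitionKey(heavy_atoms=heavy_atoms, prefix=inchikey[:2])


def build_partition(items: Iterable[tuple[str, int]]) -> dict[PartitionKey, list[str]]:
    """Group (InChIKey, heavy-atom count) pairs into sorted buckets."""
    buckets: dict[PartitionKey, set[str]] = {}
    for inchikey, hac in items:
        buckets.setdefault(partition_key(inchikey, hac), set()).add(inchikey)
    return {key: sorted(vals) for key, vals in sorted(buckets.items())}


def lookup(inchikey: str, heavy_atoms: int,
           partition: Mapping[PartitionKey, list[str]]) -> bool:
    """Membership test equivalent to a linear scan over all registered keys."""
    _check_key(inchikey)
    bucket = partition.get(PartitionKey(heavy_atoms, inchikey[:2]))
    if not bucket:
        return False
    i = bisect.bisect_left(bucket, inchikey)
    return i < len(bucket) and bucket[i] == inchikey


def write_partition(partition: Mapping[PartitionKey, list[str]], root: str | Path) -> None:
    """Persist as ``<root>/<heavy_atoms>/<prefix>.txt``, one key per line."""
    root = Path(root)
    for key, bucket in partition.items():
        directory = root / str(key.heavy_atoms)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{key.prefix}.txt").write_text("\n".join(bucket) + "\n")


def read_partition(root: str | Path) -> dict[PartitionKey, list[str]]:
    root = Path(root)
    out: dict[PartitionKey, list[str]] = {}
    for hac_dir in sorted(root.iterdir()):
        if not hac_dir.is_dir() or not hac_dir.name.isdigit():
            continue
        for path in sorted(hac_dir.glob("*.txt")):
            key = PartitionKey(int(hac_dir.name), path.stem)
            out[key] = [line for line in path.read_text().splitlines() if line]
    return out
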