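"""Scaffold census/overlap, NPR shape geometry and InChIKey partitioning."""

import random
import string

import numpy as np
import pytest

from rxnenum.diversity import (EMPTY_SCAFFOLD, PartitionKey,
                               bin_shapes, build_partition, lookup, murcko_scaffold,
                               npr_from_points, npr_shape, partition_key,
                               read_partition, scaffold_census, scaffold_overlap,
                               write_partition)


class TestScaffolds:
    def test_toluene_reduces_to_benzene(self):
        assert murcko_scaffold("Cc1ccccc1") == "c1ccccc1"

    def test_scaffold_is_fixed_point(self):
        scaffold = murcko_scaffold("CCc1ccc(CN2CCOCC2)cc1")
        assert murcko_scaffold(scaffold) == scaffold

    def test_acyclic_gives_sentinel(self):
        assert murcko_scaffold("CCCCCC") == EMPTY_SCAFFOLD

    def test_census_counts(self):
        census = scaffold_census(["Cc1ccccc1", "CCc1ccccc1", "c1ccncc1", "CCCC"])
        assert census.n_compounds == 4
        assert census.n_scaffolds == 2  # benzene + pyridine
        assert census.n_acyclic == 1
        assert census.compounds_per_scaffold == pytest.approx(2.0)
        assert census.scaffold_counts["c1ccccc1"] == 2

    def test_census_order_invariant(self):
        mols = ["Cc1ccccc1", "c1ccncc1", "CCCC", "c1ccccc1"]
        a = scaffold_census(mols)
        b = scaffold_census(reversed(mols))
        assert a.scaffold_counts == b.scaffold_counts

    def test_overlap_identical_and_disjoint(self):
        a = scaffold_census(["Cc1ccccc1", "c1ccncc1"])
        assert scaffold_overlap(a, a).fraction_a == 1.0
        b = scaffold_census(["C1CCCCC1"])
        assert scaffold_overlap(a, b).shared == 0

    def test_overlap_matches_set_oracle(self):
        lib_a = ["Cc1ccccc1", "c1ccncc1", "C1CCNCC1", "CCCC"]
        lib_b = ["CCc1ccccc1", "C1CCNCC1", "c1ccoc1"]
        result = scaffold_overlap(scaffold_census(lib_a), scaffold_census(lib_b))
        oracle = ({murcko_scaffold(s) for s in lib_a} - {EMPTY_SCAFFOLD}) \
            & ({murcko_scaffold(s) for s in lib_b} - {EMPTY_SCAFFOLD})
        assert result.shared == len(oracle) == 2


class TestNprGeometry:
    def test_linear_rod_corner(self):
        coords = np.array([[float(i), 0.0, 0.0] for i in range(10)])
        npr1, npr2 = npr_from_points(coords)
        assert npr1 == pytest.approx(0.0, abs=1e-12)
        assert npr2 == pytest.approx(1.0, abs=1e-12)

    def test_planar_ring_disc_corner(self):
        # perpendicular-axis theorem: flat body => I1 + I2 = I3
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        coords = np.stack([np.cos(angles), np.sin(angles), np.zeros(12)], axis=1)
        npr1, npr2 = npr_from_points(coords)
        assert npr1 == pytest.approx(0.5, abs=1e-12)
        assert npr2 == pytest.approx(0.5, abs=1e-12)

    def test_tetrahedron_sphere_corner(self):
        coords = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                          dtype=float)
        npr1, npr2 = npr_from_points(coords)
        assert npr1 == pytest.approx(1.0)
        assert npr2 == pytest.approx(1.0)

    def test_embedded_molecules_satisfy_triangle(self):
        for smi in ["CCCCCCCC", "c1ccc2ccccc2c1", "CC(C)(C)C", "c1ccccc1CCN",
                    "C1CCCCC1", "O=C(N)c1ccccc1"]:
            npr1, npr2 = npr_shape(smi, seed=42)
            assert npr1 <= npr2 <= 1.0 + 1e-6
            assert npr1 + npr2 >= 1.0 - 1e-6

    def test_agrees_with_reference_descriptor(self):
        """Cross-check our inertia-tensor math against RDKit's NPR descriptors
        on the same conformer."""
        from rdkit import Chem
        from rdkit.Chem import AllChem, rdMolDescriptors

        mol = Chem.AddHs(Chem.MolFromSmiles("CC(=O)OC1=C2CC(c3ccccc3)C2CCC1"))
        assert AllChem.EmbedMolecule(mol, randomSeed=42) == 0
        ours = npr_from_points(mol.GetConformer().GetPositions(),
                               np.array([a.GetMass() for a in mol.GetAtoms()]))
        assert ours[0] == pytest.approx(rdMolDescriptors.CalcNPR1(mol), abs=1e-6)
        assert ours[1] == pytest.approx(rdMolDescriptors.CalcNPR2(mol), abs=1e-6)

    def test_seed_determinism(self):
        assert npr_shape("c1ccccc1CCN", seed=7) == npr_shape("c1ccccc1CCN", seed=7)


class TestBinShapes:
    def test_single_point_single_cell(self):
        grid = bin_shapes([(0.3, 0.8)])
        assert grid.n_total == 1
        assert grid.grid.sum() == 1
        assert (grid.grid > 0).sum() == 1

    def test_identical_points_share_cell(self):
        grid = bin_shapes([(0.25, 0.85)] * 7)
        assert grid.grid.max() == 7
        assert (grid.grid > 0).sum() == 1

    def test_matches_histogram_oracle(self):
        rng = np.random.default_rng(5)
        npr2 = rng.uniform(0.5, 1.0, 300)
        npr1 = np.array([rng.uniform(max(0, 1 - y), y) for y in npr2])
        points = np.stack([npr1, npr2], axis=1)
        grid = bin_shapes(points, nbins=50)
        oracle, _, _ = np.histogram2d(npr1, npr2, bins=50,
                                      range=[[0, 1], [0.5, 1]])
        assert np.array_equal(grid.grid, oracle)
        assert grid.grid.sum() == 300

    def test_out_of_triangle_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            grid = bin_shapes([(0.9, 0.3)])
        assert grid.grid.sum() == 1


def random_inchikey(rng):
    letters = string.ascii_uppercase
    return ("".join(rng.choices(letters, k=14)) + "-"
            + "".join(rng.choices(letters, k=10)) + "-N")


class TestPartition:
    def test_benzene_partition_key(self):
        # standard InChIKey of benzene starts with "UH"; 6 heavy atoms
        from rdkit import Chem

        key = Chem.MolToInchiKey(Chem.MolFromSmiles("c1ccccc1"))
        assert partition_key(key, 6) == PartitionKey(6, "UH")

    def test_inserted_found_absent_not(self):
        keys = [(random_inchikey(random.Random(i)), 10 + i % 3) for i in range(50)]
        part = build_partition(keys)
        for ik, hac in keys:
            assert lookup(ik, hac, part)
        assert not lookup(keys[0][0], 99, part)  # right key, wrong bucket

    def test_malformed_key_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            lookup("not-an-inchikey", 6, {})

    def test_lookup_equals_linear_scan(self):
        rng = random.Random(123)
        items = [(random_inchikey(rng), rng.randint(5, 40)) for _ in range(2000)]
        part = build_partition(items)
        registered = set(items)
        queries = [rng.choice(items) for _ in range(200)] + \
            [(random_inchikey(rng), rng.randint(5, 40)) for _ in range(200)]
        for ik, hac in queries:
            assert lookup(ik, hac, part) == ((ik, hac) in registered)

    def test_directory_store_round_trip(self, tmp_path):
        rng = random.Random(7)
        items = [(random_inchikey(rng), rng.randint(6, 12)) for _ in range(100)]
        part = build_partition(items)
        write_partition(part, tmp_path)
        assert read_partition(tmp_path) == part
        # grep-compatible layout: <hac>/<prefix>.txt
        key = next(iter(part))
        assert (tmp_path / str(key.heavy_atoms) / f"{key.prefix}.txt").exists()
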