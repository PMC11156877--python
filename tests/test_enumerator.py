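"""Transform application, enumeration equivalence, purchasability, curation."""

import itertools
import warnings

import pytest
from rdkit import Chem

from rxnenum.building_blocks import BuildingBlock, Tier, filter_catalog
from rxnenum.enumerator import (EnumerationOptions, Purchasability, apply_variant,
                                assign_purchasability, curation_sample,
                                enumerate_products)
from rxnenum.reaction_registry import builtin, builtin_library


def brute_force_keys(defn, pools):
    """Independent oracle: nested loops over the full reagent cross-product,
    expanding precursors, keyed by InChIKey."""
    from rxnenum.building_blocks import apply_precursor

    keys = set()
    for variant in defn.variants:
        slot_smiles = []
        for tag in variant.component_tags:
            main = defn.resolve_tag(tag)
            smiles = [m.block.smiles for m in pools.get(main.synthon_id, [])]
            for pre in defn.precursors_for_tag(tag):
                for m in pools.get(pre.synthon_id, []):
                    smiles.extend(apply_precursor(m.block, pre))
            slot_smiles.append(smiles)
        for combo in itertools.product(*slot_smiles):
            for smi in apply_variant(variant, combo):
                keys.add(Chem.MolToInchiKey(Chem.MolFromSmiles(smi)))
    return keys


class TestApplyVariant:
    def test_thiatriazole_on_dimethylamine(self):
        variant = builtin("amino_thiatriazoles").variants[0]
        assert apply_variant(variant, ["CNC"]) == [Chem.CanonSmiles("CN(C)C1=NN=NS1")]

    def test_tetrazole_on_methylamine_and_isothiocyanate(self):
        variant = builtin("amino_tetrazoles").variants[0]
        got = apply_variant(variant, ["CN", "S=C=NC"])
        assert got == [Chem.CanonSmiles("CNC1=NN=NN1C")]

    def test_tetrazole_rejects_amide(self):
        variant = builtin("amino_tetrazoles").variants[0]
        assert apply_variant(variant, ["CC(N)=O", "S=C=NC"]) == []

    def test_beta_keto_imide_drops_acetonide_byproduct(self):
        variant = builtin("beta_keto_imides").variants[0]
        got = apply_variant(variant, ["CC1=CC(=O)OC(C)(C)O1", "CC(N)=O"])
        assert got == ["CC(=O)CC(=O)NC(C)=O"]  # no C3 acetone-derived fragment

    def test_truce_smiles_aryl_migration(self):
        variant = builtin("truce_smiles").variants[0]  # Z-H, chain 0, R2=H
        got = apply_variant(variant, ["Nc1ccccc1", "O=C(Cl)CC#N"])
        assert got == ["N#CC(C(N)=O)c1ccccc1"]

    def test_cycloaddition_2_2_bicyclooctene(self):
        variant = builtin("cycloaddition_2_2").variants[0]
        got = apply_variant(variant, ["CC(=O)OC(C)=O", "C=Cc1ccccc1"])
        assert got == ["CC(=O)OC1=C2CC(c3ccccc3)C2CCC1"]

    def test_cycloaddition_4_2_bridged_tricycle(self):
        variant = builtin("cycloaddition_4_2").variants[0]
        got = apply_variant(variant, ["CC(=O)OC(C)=O", "c1ccoc1"])
        assert got == ["CC(=O)OC1=C2C3C=CC(O3)C2CCC1"]

    def test_arity_mismatch_raises(self):
        variant = builtin("amino_tetrazoles").variants[0]
        with pytest.raises(ValueError, match="arity"):
            apply_variant(variant, ["CN"])


class TestEnumerate:
    def _products(self, rid, pools, **opts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return list(enumerate_products(builtin(rid), pools,
                                           opts=EnumerationOptions(**opts)))

    def test_one_component_pool_count(self):
        thia = builtin("amino_thiatriazoles")
        amines = [BuildingBlock.from_smiles(s, f"A{i}", Tier.BB50)
                  for i, s in enumerate(["CN", "CCN", "CCCN"])]
        pools = {"A": filter_catalog(amines, thia.synthon("A"),
                                     thia.global_exclusions)}
        products = self._products("amino_thiatriazoles", pools)
        assert len(products) == 3

    def test_two_component_cross_product(self):
        tetr = builtin("amino_tetrazoles")
        amines = filter_catalog(
            [BuildingBlock.from_smiles(s, f"A{i}", Tier.BB50)
             for i, s in enumerate(["CN", "CCN"])],
            tetr.synthon("A"), tetr.global_exclusions)
        ncs = filter_catalog(
            [BuildingBlock.from_smiles(s, f"B{i}", Tier.BB50)
             for i, s in enumerate(["S=C=NC", "S=C=NCC"])],
            tetr.synthon("B"), tetr.global_exclusions)
        products = self._products("amino_tetrazoles", {"A": amines, "B": ncs})
        assert len(products) == 4

    def test_symmetric_anhydride_yields_one_product(self):
        c22 = builtin("cycloaddition_2_2")
        anh = filter_catalog([BuildingBlock.from_smiles("CC(=O)OC(C)=O", "ANH", Tier.BB50)],
                             c22.synthon("A_ANHYDRIDE"), c22.global_exclusions)
        olefin = filter_catalog([BuildingBlock.from_smiles("C=Cc1ccccc1", "OLE", Tier.BB50)],
                                c22.synthon("B_MONOSUB"), c22.global_exclusions)
        assert anh[0].symmetric
        products = self._products("cycloaddition_2_2",
                                  {"A_ANHYDRIDE": anh, "B_MONOSUB": olefin})
        assert len(products) == 1

    @pytest.mark.parametrize("rid", [d.reaction_id for d in builtin_library()])
    def test_matches_brute_force_oracle(self, rid, small_pools):
        pools = small_pools[rid]
        got = {p.inchikey for p in self._products(rid, pools)}
        assert got == brute_force_keys(builtin(rid), pools)

    @pytest.mark.parametrize("rid", ["amino_tetrazoles", "truce_smiles"])
    def test_chunk_invariance(self, rid, small_pools):
        pools = small_pools[rid]
        big = {p.inchikey for p in self._products(rid, pools, chunk_size=2000)}
        tiny = {p.inchikey for p in self._products(rid, pools, chunk_size=1)}
        assert big == tiny

    def test_empty_pool_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning, match="empty pool"):
            out = list(enumerate_products(builtin("amino_tetrazoles"),
                                          {"A": [], "B": []}))
        assert out == []

    def test_max_products_cap(self, small_pools):
        pools = small_pools["truce_smiles"]
        assert len(self._products("truce_smiles", pools, max_products=7)) == 7

    def test_provenance_fields(self, small_pools):
        product = self._products("amino_tetrazoles",
                                 small_pools["amino_tetrazoles"])[0]
        assert product.reaction_id == "amino_tetrazoles"
        assert product.product_id.startswith("amino_tetrazoles_V1_")
        assert len(product.reagent_ids) == 2
        assert Chem.MolToInchiKey(Chem.MolFromSmiles(product.smiles)) == product.inchikey


class TestPurchasability:
    @pytest.mark.parametrize("a,b,expected", [
        (t1, t2,
         Purchasability.CODE_1 if (t1, t2) == (Tier.BB50, Tier.BB50)
         else Purchasability.CODE_2 if t1 in (Tier.BB50, Tier.BB40)
         and t2 in (Tier.BB50, Tier.BB40)
         else Purchasability.EXPENSIVE)
        for t1, t2 in itertools.product(list(Tier), repeat=2)
    ])
    def test_exhaustive_tier_pairs(self, a, b, expected):
        assert assign_purchasability([a, b]) is expected

    def test_single_reagent(self):
        assert assign_purchasability([Tier.BB50]) is Purchasability.CODE_1
        assert assign_purchasability([Tier.BB40]) is Purchasability.CODE_2
        assert assign_purchasability([Tier.BB20]) is Purchasability.EXPENSIVE

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_purchasability([])


class TestCurationSample:
    FIXTURES = ["c1ccccc1", "CCO", "CCCCCCCC", "c1ccncc1", "CC(=O)O", "CCN"]

    @staticmethod
    def _min_pairwise(smiles_list):
        from rdkit import DataStructs
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        fps = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles_list]
        return min(1 - DataStructs.TanimotoSimilarity(a, b)
                   for a, b in itertools.combinations(fps, 2))

    def test_k_equal_n_returns_all(self):
        assert curation_sample(self.FIXTURES, len(self.FIXTURES)) == self.FIXTURES

    def test_k_above_n_warns_returns_all(self):
        with pytest.warns(UserWarning):
            assert curation_sample(self.FIXTURES, 10) == self.FIXTURES

    def test_duplicates_not_both_picked(self):
        pool = ["c1ccccc1", "c1ccccc1", "CCO", "CCCCCCCC", "c1ccncc1"]
        picked = curation_sample(pool, 4, seed=3)
        assert picked.count("c1ccccc1") <= 1

    def test_matches_reference_greedy_objective(self):
        """The pick reproduces an independently coded greedy MaxMin: starting
        from the same first element, repeatedly add the molecule farthest
        (max-min Tanimoto distance) from the picked set. Verified against the
        exhaustive C(6,3)=20-subset optimum as an upper bound."""
        from rdkit import DataStructs
        from rdkit.Chem import rdFingerprintGenerator

        picked = curation_sample(self.FIXTURES, 3, seed=7)

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        fps = {s: gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in self.FIXTURES}

        def dist(a, b):
            return 1 - DataStructs.TanimotoSimilarity(fps[a], fps[b])

        reference = [picked[0]]
        while len(reference) < 3:
            reference.append(max((s for s in self.FIXTURES if s not in reference),
                                 key=lambda s: min(dist(s, p) for p in reference)))
        assert self._min_pairwise(picked) == pytest.approx(
            self._min_pairwise(reference))

        optimum = max(self._min_pairwise(list(sub))
                      for sub in itertools.combinations(self.FIXTURES, 3))
        assert self._min_pairwise(picked) <= optimum + 1e-9

    def test_deterministic_for_seed(self):
        assert curation_sample(self.FIXTURES, 3, seed=11) == \
            curation_sample(self.FIXTURES, 3, seed=11)
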