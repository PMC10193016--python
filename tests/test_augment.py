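import warnings

import pytest
from rdkit import Chem

from fragscreen.augment import (AugmentationConfig, _cut, _cuttable_bonds,
                                _environment_key, augment_dataset,
                                build_fragment_library, grow_molecule)
from fragscreen.chem import MoleculeRecord, canonicalize_smiles


def _parent_core_preserved(parent_smiles: str, analog_smiles: str) -> bool:
    """Oracle: some single-cut retained core of the parent (or the whole
    parent, for pure growth) is a substructure of the analog."""
    parent = Chem.MolFromSmiles(parent_smiles)
    analog = Chem.MolFromSmiles(analog_smiles)
    if analog.HasSubstructMatch(parent):
        return True
    for bond_idx in _cuttable_bonds(parent):
        pieces = _cut(parent, bond_idx)
        if pieces is None:
            continue
        for piece in pieces:
            rw = Chem.RWMol(piece)
            rw.RemoveAtom(next(a.GetIdx() for a in rw.GetAtoms()
                               if a.GetAtomicNum() == 0))
            core = rw.GetMol()
            try:
                Chem.SanitizeMol(core)
            except Exception:
                continue
            if analog.HasSubstructMatch(core):
                return True
    return False


class TestFragmentLibrary:
    def test_ethane_single_cut(self):
        lib = build_fragment_library(["CC"], radius=3)
        # one cuttable C-C bond; both sides are one-carbon attachments
        assert lib.entries == {"*C": {"*C"}}

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            build_fragment_library([], radius=3)

    def test_environment_keys_canonical(self):
        # two identical environments collide to one key
        lib = build_fragment_library(["CCO", "OCC"], radius=2)
        lib2 = build_fragment_library(["CCO"], radius=2)
        assert lib.entries == lib2.entries

    def test_radius_refinement_monotonic(self, small_sar):
        """A finer (larger-radius) key never admits more fragments at a
        fixed seed site than a coarser one."""
        refs = [r.smiles for r in small_sar]
        seed = MoleculeRecord(id="s", smiles=small_sar[0].smiles)
        products = {}
        for radius in (1, 3):
            lib = build_fragment_library(refs, radius=radius)
            cfg = AugmentationConfig(k=10_000, radius=radius, rng_seed=0)
            products[radius] = {a.smiles for a in grow_molecule(seed, lib, cfg)}
        assert products[3] <= products[1]

    def test_closure_reference_contains_own_cuts(self):
        smiles = "CCOc1ccccc1"
        lib = build_fragment_library([smiles], radius=3)
        mol = Chem.MolFromSmiles(smiles)
        for bond_idx in _cuttable_bonds(mol):
            pieces = _cut(mol, bond_idx)
            for retained, removed in (pieces, pieces[::-1]):
                key = _environment_key(retained, 3)
                assert Chem.MolToSmiles(removed) in lib.entries[key]


class TestGrowMolecule:
    def test_k_zero_empty(self, fragment_library):
        seed = MoleculeRecord(id="s", smiles="Cc1ccccc1", label=1)
        assert grow_molecule(seed, fragment_library,
                             AugmentationConfig(k=0, rng_seed=0)) == []

    def test_analogs_valid_unique_labeled(self, fragment_library, small_sar,
                                          aug_config):
        seed = small_sar[0]
        analogs = grow_molecule(seed, fragment_library, aug_config)
        assert len(analogs) == aug_config.k
        smiles = [a.smiles for a in analogs]
        assert len(set(smiles)) == len(smiles)
        assert seed.smiles not in smiles
        for a in analogs:
            assert a.label == seed.label
            assert a.parent_id == seed.id
            assert a.provenance == "augmented"
            assert canonicalize_smiles(a.smiles) == a.smiles  # fixed point

    def test_conservatism_core_preserved(self, fragment_library, small_sar,
                                         aug_config):
        for seed in small_sar[:4]:
            for analog in grow_molecule(seed, fragment_library, aug_config):
                assert _parent_core_preserved(seed.smiles, analog.smiles), (
                    seed.smiles, analog.smiles)

    def test_deterministic_given_seed(self, fragment_library, small_sar):
        seed = small_sar[1]
        cfg = AugmentationConfig(k=8, rng_seed=42)
        first = [a.smiles for a in grow_molecule(seed, fragment_library, cfg)]
        second = [a.smiles for a in grow_molecule(seed, fragment_library, cfg)]
        assert first == second
        other = [a.smiles for a in grow_molecule(
            seed, fragment_library, AugmentationConfig(k=8, rng_seed=43))]
        assert first != other  # different stream, overwhelmingly

    def test_shortfall_warns_and_strict_raises(self):
        tiny_lib = build_fragment_library(["CC"], radius=3)
        seed = MoleculeRecord(id="s", smiles="CCO", label=0)
        with pytest.warns(UserWarning, match="unique analogs"):
            got = grow_molecule(seed, tiny_lib,
                                AugmentationConfig(k=50, rng_seed=0))
        assert 0 < len(got) < 50
        with pytest.raises(RuntimeError):
            grow_molecule(seed, tiny_lib,
                          AugmentationConfig(k=50, rng_seed=0, strict=True))


class TestAugmentDataset:
    def test_counts_dedup_and_labels(self, fragment_library, small_sar,
                                     aug_config):
        out = augment_dataset(small_sar, fragment_library, aug_config)
        assert len(out) == len(small_sar) * (1 + aug_config.k)
        smiles = [r.smiles for r in out]
        assert len(set(smiles)) == len(smiles)  # global dedup
        by_id = {r.id: r for r in out}
        for r in out:
            if r.provenance == "augmented":
                assert r.label == by_id[r.parent_id].label

    def test_unlabeled_seed_rejected(self, fragment_library, aug_config):
        with pytest.raises(ValueError, match="unlabeled"):
            augment_dataset([MoleculeRecord(id="x", smiles="CCO")],
                            fragment_library, aug_config)

    def test_byte_identical_rerun(self, fragment_library, small_sar):
        cfg = AugmentationConfig(k=3, rng_seed=9)
        a = [(r.id, r.smiles) for r in
             augment_dataset(small_sar, fragment_library, cfg)]
        b = [(r.id, r.smiles) for r in
             augment_dataset(small_sar, fragment_library, cfg)]
        assert a == b
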