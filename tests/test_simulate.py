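import itertools

import numpy as np
import pytest
from rdkit import Chem, DataStructs

from ms2struct.chem import Molecule, is_valid_smiles, morgan_fingerprint
from ms2struct.simulate import (
    SimConfig,
    augment_by_energy,
    availability_strata,
    build_dataset,
    generate_library,
    partition_dataset,
    simulate_spectrum,
)
from ms2struct.spectra import PrecursorMode, bin_spectrum, normalize_intensities


class TestLibrary:
    def test_deterministic_for_seed(self):
        cfg = SimConfig(n_molecules=100, seed=7)
        a = [m.canonical_smiles for m in generate_library(cfg)]
        b = [m.canonical_smiles for m in generate_library(cfg)]
        assert a == b

    def test_seed_changes_library(self):
        a = [m.canonical_smiles for m in generate_library(SimConfig(n_molecules=100, seed=7))]
        b = [m.canonical_smiles for m in generate_library(SimConfig(n_molecules=100, seed=8))]
        assert a != b

    def test_contract_valid_distinct_bounded(self, small_library):
        smiles = [m.canonical_smiles for m in small_library]
        assert len(set(smiles)) == len(smiles)
        for mol in small_library:
            assert is_valid_smiles(mol.canonical_smiles)
            assert mol.n_heavy <= 16


class TestFragmentation:
    def test_ethanol_expected_fragment_masses(self):
        spec = simulate_spectrum(Molecule.from_smiles("CCO"), PrecursorMode.POS, 35.0, seed=0)
        mzs = [mz for mz, _ in spec.peaks]
        # CH3+, OH+, C2H5+, CH2OH+ cleavage ions and the [M+H]+ precursor
        for expected in (16.031, 18.010, 30.046, 32.026, 47.049):
            assert min(abs(m - expected) for m in mzs) < 0.005

    def test_ring_only_molecule_precursor_only(self):
        spec = simulate_spectrum(Molecule.from_smiles("c1ccccc1"), PrecursorMode.POS, 35.0, seed=0)
        assert len(spec.peaks) == 1
        assert spec.peaks[0][0] == pytest.approx(79.054, abs=0.005)

    def test_negative_mode_shifts_down(self):
        pos = simulate_spectrum(Molecule.from_smiles("CCO"), PrecursorMode.POS, 35.0, seed=0)
        neg = simulate_spectrum(Molecule.from_smiles("CCO"), PrecursorMode.NEG, 35.0, seed=0)
        assert max(m for m, _ in neg.peaks) == pytest.approx(
            max(m for m, _ in pos.peaks) - 2 * 1.00728, abs=1e-6
        )

    def test_deterministic(self):
        mol = Molecule.from_smiles("CCOC(C)C")
        a = simulate_spectrum(mol, PrecursorMode.POS, 130.0, seed=5)
        b = simulate_spectrum(mol, PrecursorMode.POS, 130.0, seed=5)
        assert a.peaks == b.peaks

    def test_high_energy_fragments_more(self, small_library):
        mol = next(m for m in small_library if m.n_heavy >= 8)
        low = simulate_spectrum(mol, PrecursorMode.POS, 35.0, seed=1)
        high = simulate_spectrum(mol, PrecursorMode.POS, 130.0, seed=1)
        assert len(high.peaks) >= len(low.peaks)

    def test_mass_conservation_of_level1_pairs(self, small_library):
        """Neutral masses of each cleavage pair sum to the parent mass."""
        from ms2struct.simulate import _cleavages, _fragment_mass

        for mol in small_library[:25]:
            rdmol = Chem.MolFromSmiles(mol.canonical_smiles)
            atoms = frozenset(range(rdmol.GetNumAtoms()))
            parent = _fragment_mass(rdmol, atoms)
            for side_a, side_b in _cleavages(rdmol, atoms):
                total = _fragment_mass(rdmol, side_a) + _fragment_mass(rdmol, side_b)
                assert total == pytest.approx(parent, abs=1e-3)

    def test_spectra_discriminate_structures(self, small_library):
        """Structurally dissimilar pairs rarely produce near-identical spectra."""
        mols = small_library[:60]
        fps = [morgan_fingerprint(m.canonical_smiles) for m in mols]
        vecs = []
        for i, m in enumerate(mols):
            spec = simulate_spectrum(m, PrecursorMode.POS, 35.0, seed=i)
            vecs.append(normalize_intensities(bin_spectrum(spec, 1.0, 500.0)))
        checked, confusable = 0, 0
        for i, j in itertools.combinations(range(len(mols)), 2):
            tani = DataStructs.TanimotoSimilarity(fps[i], fps[j])
            if tani >= 0.3:
                continue
            checked += 1
            denom = np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j])
            cos = float(vecs[i] @ vecs[j] / denom) if denom > 0 else 0.0
            confusable += cos >= 0.9
        assert checked > 100
        assert confusable / checked < 0.10


class TestDataset:
    def test_no_missing_when_rate_zero(self):
        ds = build_dataset(SimConfig(n_molecules=40, seed=1, missing_rate=0.0))
        assert all(len(inst.spectra) == 4 for inst in ds)

    def test_at_least_one_spectrum_guaranteed(self):
        ds = build_dataset(SimConfig(n_molecules=120, seed=2, missing_rate=0.9))
        assert all(len(inst.spectra) >= 1 for inst in ds)

    def test_strata_sum_to_total(self, small_dataset):
        strata = availability_strata(small_dataset)
        assert sum(strata.values()) == len(small_dataset)
        assert set(strata) == {1, 2, 3, 4}


class TestAugmentation:
    def test_training_split_doubles(self, small_dataset):
        cfg = SimConfig(n_molecules=250, max_heavy_atoms=16, seed=7)
        n_train = sum(1 for i in small_dataset if i.split == "train")
        augmented = augment_by_energy(small_dataset, 5.0, cfg)
        assert sum(1 for i in augmented if i.split == "train") == 2 * n_train

    def test_twin_shares_molecule_and_channels(self, small_dataset):
        cfg = SimConfig(n_molecules=250, max_heavy_atoms=16, seed=7)
        augmented = augment_by_energy(small_dataset, 5.0, cfg)
        originals = [i for i in augmented if i.split == "train"]
        half = len(originals) // 2
        for orig, twin in zip(originals[:half], originals[half:]):
            assert orig.molecule.canonical_smiles == twin.molecule.canonical_smiles
            assert {(s.precursor_mode, s.energy_level) for s in orig.spectra} == {
                (s.precursor_mode, s.energy_level) for s in twin.spectra
            }

    def test_other_splits_untouched(self, small_dataset):
        cfg = SimConfig(n_molecules=250, max_heavy_atoms=16, seed=7)
        augmented = augment_by_energy(small_dataset, 5.0, cfg)
        for split in ("val", "test"):
            assert sum(1 for i in augmented if i.split == split) == sum(
                1 for i in small_dataset if i.split == split
            )


class TestPartition:
    def test_test_set_is_tanimoto_novel(self, small_library):
        """Brute-force all-pairs check of the exclusion guarantee."""
        cutoff = 0.9
        assignment = partition_dataset(small_library, tanimoto_cutoff=cutoff, seed=5)
        fps = {
            m.canonical_smiles: morgan_fingerprint(m.canonical_smiles)
            for m in small_library
        }
        test = [s for s, sp in assignment.items() if sp == "test"]
        rest = [s for s, sp in assignment.items() if sp != "test"]
        assert test and rest
        for t in test:
            sims = DataStructs.BulkTanimotoSimilarity(fps[t], [fps[r] for r in rest])
            assert max(sims) < cutoff

    def test_deterministic(self, small_library):
        a = partition_dataset(small_library, seed=9)
        b = partition_dataset(small_library, seed=9)
        assert a == b

    def test_degenerate_cutoff_disjoint(self, small_library):
        assignment = partition_dataset(small_library, tanimoto_cutoff=1.0, seed=3)
        splits = set(assignment.values())
        assert splits == {"train", "val", "test"}

    def test_impossible_quota_raises(self, small_library):
        with pytest.raises(RuntimeError, match="Tanimoto"):
            partition_dataset(small_library, frac_test=0.5, tanimoto_cutoff=0.01, seed=1)
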