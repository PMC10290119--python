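"""Synthetic molecule library and toy MS/MS fragmentation simulator.

Real tandem-MS training libraries are commercial, so this module provides a
desk-scale stand-in with the same *shape*: a library of small organic
molecules, up to four spectra per molecule ({[M+H]+, [M-H]-} x {35%, 130%
NCE}) with missing-spectrum cases, collision-energy augmentation, and
fingerprint-disjoint train/val/test partitioning.

The fragmentation model is deliberately simple and fully deterministic:
every acyclic bond of the molecular graph is cleaved once (twice at high
collision energy), fragment ions keep the hydrogens they carried in the
parent, and intensities decay exponentially with distance from half the
parent's heavy-atom count. Its purpose is to give the spectra encoder a
learnable, structure-dependent signal — not chemical realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, RWMol

from .chem import Molecule, canonicalize, morgan_fingerprint
from .spectra import (
    HIGH_NCE,
    LOW_NCE,
    PROTON_MASS,
    EnergyLevel,
    PrecursorMode,
    SpectrumRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "DatasetInstance",
    "generate_library",
    "simulate_spectrum",
    "build_dataset",
    "availability_strata",
    "augment_by_energy",
    "partition_dataset",
]

H_MASS = 1.00783  # monoisotopic hydrogen, Da


@dataclass(frozen=True)
class SimConfig:
    """Dataset-generation settings.

    ``missing_rate`` is the independent per-spectrum deletion probability;
    0.29 reproduces the overall fraction of absent channels implied by the
    spectra-availability strata of the reference library this generator
    emulates. ``intensity_decay`` controls how sharply fragment abundance
    falls off with fragment size asymmetry.
    """

    n_molecules: int = 2000
    max_heavy_atoms: int = 20
    seed: int = 0
    energy_low_nce: float = LOW_NCE
    energy_high_nce: float = HIGH_NCE
    missing_rate: float = 0.29
    intensity_decay: float = 0.5
    frac_val: float = 1.0 / 23.0
    frac_test: float = 1.0 / 23.0
    tanimoto_cutoff: float = 0.9

    def __post_init__(self) -> None:
        if self.n_molecules <= 0 or self.max_heavy_atoms <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.intensity_decay <= 0:
            raise ValueError("intensity_decay must be positive")


@dataclass
class DatasetInstance:
    """One molecule with its (up to four) spectra and a split label."""

    molecule: Molecule
    spectra: list[SpectrumRecord]
    split: str = "train"

    def __post_init__(self) -> None:
        keys = [(s.precursor_mode, s.energy_level) for s in self.spectra]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (precursor, energy) spectrum")
        if not self.spectra:
            raise ValueError("instance must retain at least one spectrum")


# -- library generation ------------------------------------------------------

_SCAFFOLDS = [
    "CC", "CCC", "CCCC", "CCCCC", "CCOC", "CCNC",
    "C1CCCC1", "C1CCCCC1", "C1CCOC1", "C1CCOCC1", "C1CCNC1", "C1CCNCC1",
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
]

# Substituents attach through their first atom by a single bond.
_SUBSTITUENTS = [
    "C", "C", "CC", "CCC", "C(C)C", "O", "O", "N", "N(C)C", "OC",
    "F", "Cl", "Br", "S", "SC", "C(=O)O", "C(=O)C", "C#N", "CO", "CN",
]


def _attach(core: Chem.Mol, substituent: str, host_idx: int) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(substituent)
    combined = RWMol(Chem.CombineMols(core, frag))
    combined.AddBond(host_idx, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combined.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _random_molecule(rng: np.random.Generator, max_heavy: int) -> str | None:
    core = Chem.MolFromSmiles(_SCAFFOLDS[rng.integers(len(_SCAFFOLDS))])
    n_subst = int(rng.integers(0, 5))
    for _ in range(n_subst):
        candidates = [
            a.GetIdx()
            for a in core.GetAtoms()
            if a.GetTotalNumHs() >= 1 and a.GetSymbol() in ("C", "N")
        ]
        if not candidates:
            break
        host = candidates[rng.integers(len(candidates))]
        sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
        if core.GetNumAtoms() + Chem.MolFromSmiles(sub).GetNumAtoms() > max_heavy:
            continue
        grown = _attach(core, sub, host)
        if grown is not None:
            core = grown
    if core.GetNumAtoms() > max_heavy:
        return None
    return Chem.MolToSmiles(core, isomericSmiles=False)


def generate_library(config: SimConfig) -> list[Molecule]:
    """Seeded random molecule library: scaffold + substituent assembly.

    Molecules are distinct by canonical SMILES, valid, stereo-free, and
    bounded by ``max_heavy_atoms``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    library: list[Molecule] = []
    budget = 200 * config.n_molecules
    attempts = 0
    while len(library) < config.n_molecules:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not assemble {config.n_molecules} distinct molecules "
                f"within {budget} attempts; raise max_heavy_atoms "
                f"(got {len(library)} so far)"
            )
        smiles = _random_molecule(rng, config.max_heavy_atoms)
        if smiles is None:
            continue
        canonical = canonicalize(smiles)
        if canonical in seen:
            continue
        seen.add(canonical)
        library.append(Molecule.from_smiles(canonical))
    return library


# -- toy fragmentation -------------------------------------------------------


def _mono_mass(symbol: str) -> float:
    return Chem.GetPeriodicTable().GetMostCommonIsotopeMass(symbol)


def _fragment_mass(mol: Chem.Mol, atom_ids: frozenset[int]) -> float:
    """Neutral fragment mass: atoms keep the hydrogens they had in the parent."""
    total = 0.0
    for idx in atom_ids:
        atom = mol.GetAtomWithIdx(idx)
        total += _mono_mass(atom.GetSymbol()) + atom.GetTotalNumHs() * H_MASS
    return total


def _split_on_bond(
    mol: Chem.Mol, atom_ids: frozenset[int], bond: Chem.Bond
) -> tuple[frozenset[int], frozenset[int]] | None:
    """Partition ``atom_ids`` by removing one acyclic bond inside the set."""
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    if a not in atom_ids or b not in atom_ids:
        return None
    # BFS from a avoiding the cleaved bond, restricted to the fragment.
    component = {a}
    frontier = [a]
    while frontier:
        current = frontier.pop()
        for nbr in mol.GetAtomWithIdx(current).GetNeighbors():
            j = nbr.GetIdx()
            if j not in atom_ids or j in component:
                continue
            if {current, j} == {a, b}:
                continue
            component.add(j)
            frontier.append(j)
    side_a = frozenset(component)
    side_b = atom_ids - side_a
    if not side_b:
        return None  # bond was part of a cycle within the fragment
    return side_a, side_b


def _cleavages(
    mol: Chem.Mol, atom_ids: frozenset[int]
) -> list[tuple[frozenset[int], frozenset[int]]]:
    pairs = []
    for bond in mol.GetBonds():
        if bond.IsInRing():
            continue
        split = _split_on_bond(mol, atom_ids, bond)
        if split is not None:
            pairs.append(split)
    return pairs


def simulate_spectrum(
    mol: Molecule,
    mode: PrecursorMode,
    nce: float,
    seed: int,
    intensity_decay: float = 0.5,
) -> SpectrumRecord:
    """Deterministic toy fragmentation of one molecule.

    Every acyclic bond is cleaved once; at NCE >= 100 each first-level
    fragment is cleaved one more round. A fragment with ``k`` heavy atoms in
    a parent with ``n`` gets intensity ``exp(-decay * |k - n/2|)`` (scaled so
    the strongest fragment is 999), the precursor ion is added at
    ``999 * exp(-nce/100)``, and the seed applies a small (+-5%) deterministic
    intensity jitter emulating instrument variation. Fragment ion m/z is the
    neutral fragment mass +- 1.00728 Da by precursor mode. Peaks closer than
    0.01 Da merge; ring-only molecules yield a precursor-only spectrum.
    """
    if nce <= 0:
        raise ValueError("nce must be positive")
    rdmol = Chem.MolFromSmiles(mol.canonical_smiles)
    all_atoms = frozenset(range(rdmol.GetNumAtoms()))
    parent_mass = _fragment_mass(rdmol, all_atoms)
    n_half = rdmol.GetNumAtoms() / 2.0

    fragments: list[frozenset[int]] = []
    level1 = _cleavages(rdmol, all_atoms)
    for side_a, side_b in level1:
        fragments.extend((side_a, side_b))
        if nce >= 100.0:
            for side in (side_a, side_b):
                for sub_a, sub_b in _cleavages(rdmol, side):
                    fragments.extend((sub_a, sub_b))

    rng = np.random.default_rng(seed)
    sign = 1.0 if mode is PrecursorMode.POS else -1.0
    raw: list[tuple[float, float]] = []
    if fragments:
        weights = np.array(
            [np.exp(-intensity_decay * abs(len(f) - n_half)) for f in fragments]
        )
        weights *= 999.0 / weights.max()
        for frag, w in zip(fragments, weights):
            mz = _fragment_mass(rdmol, frag) + sign * PROTON_MASS
            raw.append((mz, float(w)))
    raw.append((parent_mass + sign * PROTON_MASS, 999.0 * np.exp(-nce / 100.0)))

    jitter = 1.0 + 0.05 * rng.uniform(-1.0, 1.0, size=len(raw))
    raw = [(mz, i * j) for (mz, i), j in zip(sorted(raw), jitter)]

    merged: list[tuple[float, float]] = []
    for mz, intensity in raw:
        if merged and mz - merged[-1][0] < 0.01:
            merged[-1] = (merged[-1][0], merged[-1][1] + intensity)
        else:
            merged.append((mz, intensity))

    return SpectrumRecord(
        peaks=merged,
        precursor_mode=mode,
        energy_level=EnergyLevel.LOW if nce < 100.0 else EnergyLevel.HIGH,
        nce=nce,
        molecule_id=mol.canonical_smiles,
    )


# -- dataset assembly --------------------------------------------------------

_CONDITIONS: tuple[tuple[PrecursorMode, str], ...] = (
    (PrecursorMode.POS, "low"),
    (PrecursorMode.POS, "high"),
    (PrecursorMode.NEG, "low"),
    (PrecursorMode.NEG, "high"),
)


def _simulate_instance(
    mol: Molecule, mol_index: int, config: SimConfig, nce_shift: float = 0.0
) -> list[SpectrumRecord]:
    records = []
    for ch, (pmode, level) in enumerate(_CONDITIONS):
        nce = config.energy_low_nce if level == "low" else config.energy_high_nce
        records.append(
            simulate_spectrum(
                mol,
                pmode,
                nce + nce_shift,
                seed=(config.seed * 1_000_003 + mol_index * 7 + ch) % (2**31),
                intensity_decay=config.intensity_decay,
            )
        )
    return records


def build_dataset(config: SimConfig) -> list[DatasetInstance]:
    """Library + simulated spectra + missing-spectrum injection + splits.

    Each of the four spectra is deleted independently with probability
    ``missing_rate``; if all four are deleted one is re-added so every
    instance keeps at least one spectrum.
    """
    library = generate_library(config)
    rng = np.random.default_rng(config.seed + 1)
    splits = partition_dataset(
        library,
        frac_val=config.frac_val,
        frac_test=config.frac_test,
        tanimoto_cutoff=config.tanimoto_cutoff,
        seed=config.seed + 2,
    )
    instances = []
    for i, mol in enumerate(library):
        records = _simulate_instance(mol, i, config)
        keep = rng.random(4) >= config.missing_rate
        if not keep.any():
            keep[rng.integers(4)] = True
        kept = [r for r, k in zip(records, keep) if k]
        instances.append(
            DatasetInstance(
                molecule=mol, spectra=kept, split=splits[mol.canonical_smiles]
            )
        )
    return instances


def availability_strata(instances: list[DatasetInstance]) -> dict[int, int]:
    """Counts of instances with 4/3/2/1 available spectra."""
    strata = {4: 0, 3: 0, 2: 0, 1: 0}
    for inst in instances:
        strata[len(inst.spectra)] += 1
    return strata


def augment_by_energy(
    dataset: list[DatasetInstance],
    nce_jitter: float = 5.0,
    config: SimConfig | None = None,
) -> list[DatasetInstance]:
    """Energy-perturbation augmentation of the training split.

    Each training instance gains a twin whose spectra are re-simulated at
    NCE shifted by +-``nce_jitter`` (sign drawn per instance, seeded),
    standing in for picking the closest-energy replicate from a larger
    library. Channel availability and the target molecule are unchanged;
    validation and test are untouched. The training split doubles.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed + 3)
    augmented = list(dataset)
    for i, inst in enumerate(dataset):
        if inst.split != "train":
            continue
        shift = float(nce_jitter) * (1.0 if rng.random() < 0.5 else -1.0)
        fresh = _simulate_instance(inst.molecule, i, config, nce_shift=shift)
        present = {(s.precursor_mode, s.energy_level) for s in inst.spectra}
        kept = [
            r for r in fresh if (r.precursor_mode, r.energy_level) in present
        ]
        augmented.append(
            DatasetInstance(molecule=inst.molecule, spectra=kept, split="train")
        )
    return augmented


def partition_dataset(
    molecules: list[Molecule],
    frac_val: float = 1.0 / 23.0,
    frac_test: float = 1.0 / 23.0,
    tanimoto_cutoff: float = 0.9,
    seed: int = 0,
) -> dict[str, str]:
    """Assign train/val/test so the test set is structurally novel.

    A seeded shuffle proposes test candidates; a candidate enters the test
    set only if its maximum Morgan (radius 2, 1024-bit) Tanimoto similarity
    to every remaining train/val molecule is below ``tanimoto_cutoff``.
    Rejected candidates stay in train; the validation set is then drawn
    uniformly from the remainder.
    """
    if not (0 < frac_val and 0 < frac_test and frac_val + frac_test < 1):
        raise ValueError("fractions must be positive and sum below 1")
    n = len(molecules)
    n_test = max(1, round(frac_test * n))
    n_val = max(1, round(frac_val * n))
    fps = [morgan_fingerprint(m.canonical_smiles) for m in molecules]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    test_idx: list[int] = []
    test_set: set[int] = set()
    for idx in order:
        if len(test_idx) == n_test:
            break
        rest = [fps[j] for j in range(n) if j != idx and j not in test_set]
        max_sim = max(DataStructs.BulkTanimotoSimilarity(fps[idx], rest), default=0.0)
        if max_sim < tanimoto_cutoff:
            test_idx.append(int(idx))
            test_set.add(int(idx))
    if len(test_idx) < n_test:
        raise RuntimeError(
            f"only {len(test_idx)} of {n_test} requested test molecules satisfy "
            f"max Tanimoto < {tanimoto_cutoff}; lower the cutoff or the quota"
        )

    remainder = [i for i in order if i not in test_set]
    val_idx = set(int(i) for i in remainder[:n_val])
    assignment = {}
    for i, mol in enumerate(molecules):
        if i in test_set:
            assignment[mol.canonical_smiles] = "test"
        elif i in val_idx:
            assignment[mol.canonical_smiles] = "val"
        else:
            assignment[mol.canonical_smiles] = "train"
    return assignment
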