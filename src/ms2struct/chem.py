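"""SMILES handling: canonicalization, randomization, tokenization, formulas.

All structure handling in this package goes through stereochemistry-free
canonical SMILES: stereo descriptors cannot be recovered from fragment
masses, so they are stripped on input and never re-introduced. Multi-fragment
(dot-disconnected) SMILES are rejected everywhere — salts and mixtures are
out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "TokenVocabulary",
    "SmilesParseError",
    "canonicalize",
    "randomize_smiles",
    "formula_of",
    "mol_weight_of",
    "is_valid_smiles",
    "tokenize",
    "detokenize",
]

START = "<start>"
END = "<end>"
PAD = "<pad>"
UNK = "<unk>"
SPECIAL_TOKENS = (PAD, START, END, UNK)

# Standard SMILES token regex: bracket atoms, two-letter halogens and the
# organic subset are single tokens; ring-closure digits and %nn included.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFI]|[bcnops]|\d|[=#$:/\\\-+()."
    r"@*~])"
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed as a single molecule."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise SmilesParseError(
            f"multi-fragment SMILES rejected (salts/mixtures unsupported): {smiles!r}"
        )
    return mol


def canonicalize(smiles: str) -> str:
    """Return the unique stereo-free canonical SMILES (RDKit algorithm).

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.
    Raises :class:`SmilesParseError` on invalid input.
    """
    mol = _mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol, canonical=True, isomericSmiles=False)


def randomize_smiles(smiles: str, seed: int) -> str:
    """Return an alternative valid SMILES of the same molecule.

    The atom ordering is drawn from ``seed`` (deterministic), so different
    seeds enumerate different surface forms while the underlying molecule —
    and hence ``canonicalize`` of the output — is unchanged.
    """
    import numpy as np

    mol = _mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    rng = np.random.default_rng(seed)
    order = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
    shuffled = Chem.RenumberAtoms(mol, order)
    return Chem.MolToSmiles(shuffled, canonical=False, isomericSmiles=False)


def formula_of(smiles: str) -> dict[str, int]:
    """Element-count map including implicit hydrogens under key ``"H"``."""
    mol = _mol_from_smiles(smiles)
    counts: dict[str, int] = {}
    n_h = 0
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        n_h += atom.GetTotalNumHs()
    if n_h:
        counts["H"] = counts.get("H", 0) + n_h
    return counts


def mol_weight_of(smiles: str, *, monoisotopic: bool = False) -> float:
    """Molecular weight in Daltons (average by default, incl. hydrogens)."""
    mol = _mol_from_smiles(smiles)
    if monoisotopic:
        return float(Descriptors.ExactMolWt(mol))
    return float(Descriptors.MolWt(mol))


def is_valid_smiles(smiles: str) -> bool:
    """True iff the string parses as a single-fragment molecule."""
    try:
        _mol_from_smiles(smiles)
    except SmilesParseError:
        return False
    return True


@dataclass(frozen=True)
class Molecule:
    """A stereo-free molecule: the unit of structure across the package."""

    canonical_smiles: str
    formula: dict[str, int] = field(compare=False)
    mol_weight: float = field(compare=False)
    n_heavy: int = field(compare=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        canonical = canonicalize(smiles)
        formula = formula_of(canonical)
        return cls(
            canonical_smiles=canonical,
            formula=formula,
            mol_weight=mol_weight_of(canonical),
            n_heavy=sum(v for k, v in formula.items() if k != "H"),
        )

    def __hash__(self) -> int:  # frozen dataclass with dict field
        return hash(self.canonical_smiles)


_MORGAN_GEN = None


def morgan_fingerprint(smiles: str):
    """Morgan circular fingerprint, radius 2 folded to 1024 bits.

    This is the fingerprint used both for train/test disjointness checks
    and for fingerprint-cosine evaluation.
    """
    global _MORGAN_GEN
    from rdkit.Chem import rdFingerprintGenerator

    if _MORGAN_GEN is None:
        _MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
    return _MORGAN_GEN.GetFingerprint(_mol_from_smiles(smiles))


def smiles_tokens(smiles: str) -> list[str]:
    """Split a SMILES string into chemically atomic tokens.

    Two-letter elements (Cl, Br) and bracket atoms are single tokens; a
    character-per-character split would corrupt them.
    """
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"SMILES contains untokenizable characters: {smiles!r}")
    return tokens


@dataclass
class TokenVocabulary:
    """Bijective token <-> integer-id mapping with reserved special tokens."""

    tokens: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        for special in SPECIAL_TOKENS:
            if self.tokens.count(special) != 1:
                raise ValueError(f"special token {special} must occur exactly once")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_corpus(cls, smiles_iter) -> "TokenVocabulary":
        seen: set[str] = set()
        for s in smiles_iter:
            seen.update(smiles_tokens(s))
        return cls(list(SPECIAL_TOKENS) + sorted(seen))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def start_id(self) -> int:
        return self.index[START]

    @property
    def end_id(self) -> int:
        return self.index[END]

    @property
    def unk_id(self) -> int:
        return self.index[UNK]


def tokenize(
    smiles: str, vocab: TokenVocabulary, *, allow_unknown: bool = False
) -> list[int]:
    """Encode a SMILES as ids, framed by ``<start>`` ... ``<end>``.

    Unknown tokens raise by default; with ``allow_unknown`` they map to
    ``<unk>`` (used during training where randomized forms may stray from
    the vocabulary-building sample).
    """
    ids = [vocab.start_id]
    for tok in smiles_tokens(smiles):
        if tok in vocab.index:
            ids.append(vocab.index[tok])
        elif allow_unknown:
            ids.append(vocab.unk_id)
        else:
            raise KeyError(f"token {tok!r} not in vocabulary")
    ids.append(vocab.end_id)
    return ids


def detokenize(ids, vocab: TokenVocabulary) -> str:
    """Inverse of :func:`tokenize`; special tokens are dropped."""
    specials = {vocab.pad_id, vocab.start_id, vocab.end_id, vocab.unk_id}
    return "".join(vocab.tokens[i] for i in ids if i not in specials)
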