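"""Candidate structure generation and molecular-weight ranking.

Two complementary routes produce candidates for a query spectra embedding:

* **direct** — decode the embedding itself many times with pure sampling and
  keep the valid, deduplicated SMILES (can propose novel molecules);
* **indirect** — retrieve the nearest SMILES embeddings from a reference
  molecule pool and decode those (anchors the answer in known chemistry).

The union is ranked by absolute discrepancy from the expected molecular
weight — which is taken as known, since the precursor mass is read directly
off the spectrum — and truncated to the top ``top_k`` (default 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .autoencoder import SmilesAutoencoder
from .chem import Molecule, is_valid_smiles
from .spectra import PROTON_MASS, ChannelTensor, PrecursorMode, SpectrumRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateSource",
    "Candidate",
    "CandidateSet",
    "EmbeddingIndex",
    "direct_generate",
    "build_index",
    "indirect_generate",
    "recommend",
    "estimate_reference_mw",
]


class CandidateSource(str, Enum):
    DIRECT = "direct"
    INDIRECT = "indirect"


@dataclass(frozen=True)
class Candidate:
    molecule: Molecule
    source: CandidateSource
    mw_discrepancy: float


@dataclass
class CandidateSet:
    """Deduplicated, MW-ranked recommendations for one query."""

    query_id: str
    reference_mw: float
    candidates: list[Candidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def smiles(self) -> list[str]:
        return [c.molecule.canonical_smiles for c in self.candidates]


@dataclass
class EmbeddingIndex:
    """Flat Euclidean nearest-neighbor index over (embedding, SMILES) pairs."""

    embeddings: np.ndarray  # (N, d)
    smiles: list[str]

    def __post_init__(self) -> None:
        if len(self.smiles) != self.embeddings.shape[0]:
            raise ValueError("embedding/SMILES count mismatch")
        if len(set(self.smiles)) != len(self.smiles):
            raise ValueError("duplicate SMILES in index")

    def __len__(self) -> int:
        return len(self.smiles)

    def nearest(self, query: np.ndarray, k: int) -> list[tuple[float, str, np.ndarray]]:
        """k nearest entries, distance-sorted; ties break lexicographically."""
        if len(self) == 0:
            raise ValueError("empty index")
        if k > len(self):
            raise ValueError(f"k={k} exceeds index size {len(self)}")
        dists = np.linalg.norm(self.embeddings - query[None, :], axis=1)
        order = sorted(range(len(self)), key=lambda i: (dists[i], self.smiles[i]))[:k]
        return [(float(dists[i]), self.smiles[i], self.embeddings[i]) for i in order]


def direct_generate(
    ae: SmilesAutoencoder, emb: np.ndarray, n_samples: int = 100, seed: int = 0
) -> list[Molecule]:
    """Pure-sampling decodes of the query embedding, filtered to valid SMILES.

    Survivors are canonicalized and deduplicated; the validity rate is
    logged. May legitimately return an empty list for a hard embedding.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    embs = np.repeat(np.asarray(emb)[None, :], n_samples, axis=0)
    decoded = ae.decode_embeddings(embs, mode="sample", seed=seed)
    molecules: dict[str, Molecule] = {}
    n_valid = 0
    for smiles in decoded:
        if not is_valid_smiles(smiles):
            continue
        n_valid += 1
        mol = Molecule.from_smiles(smiles)
        molecules.setdefault(mol.canonical_smiles, mol)
    logger.info(
        "direct generation: %d/%d samples valid (%.0f%%), %d unique",
        n_valid, n_samples, 100.0 * n_valid / n_samples, len(molecules),
    )
    return list(molecules.values())


def build_index(pool: list[Molecule], ae: SmilesAutoencoder) -> EmbeddingIndex:
    """Embed a molecule pool (e.g. the AE training set) for retrieval."""
    unique: dict[str, Molecule] = {m.canonical_smiles: m for m in pool}
    smiles = sorted(unique)
    chunks = []
    for i in range(0, len(smiles), 256):
        chunks.append(ae.encode_batch(smiles[i : i + 256]))
    return EmbeddingIndex(embeddings=np.concatenate(chunks, axis=0), smiles=smiles)


def indirect_generate(
    index: EmbeddingIndex,
    emb: np.ndarray,
    k: int = 20,
    ae: SmilesAutoencoder | None = None,
) -> list[Molecule]:
    """Nearest-embedding retrieval from the pool, then decode.

    The k closest pool embeddings are decoded back to SMILES (greedy); when
    a decode is invalid the stored pool SMILES stands in, so retrieval never
    loses a neighbor to decoder error.
    """
    neighbors = index.nearest(np.asarray(emb), k)
    molecules: dict[str, Molecule] = {}
    for _, pool_smiles, pool_emb in neighbors:
        smiles = pool_smiles
        if ae is not None:
            decoded = ae.decode_embedding(pool_emb, mode="greedy")
            if is_valid_smiles(decoded):
                smiles = decoded
        mol = Molecule.from_smiles(smiles)
        molecules.setdefault(mol.canonical_smiles, mol)
    return list(molecules.values())


def estimate_reference_mw(records: list[SpectrumRecord]) -> float:
    """Convenience precursor-mass reader: highest-m/z peak corrected by mode.

    The expected molecular weight is normally supplied by the user; this
    helper recovers it from the precursor peak ([M+H]+ minus / [M-H]- plus
    1.00728 Da) when it is not.
    """
    best = None
    for rec in records:
        for mz, _ in rec.peaks:
            neutral = mz - PROTON_MASS if rec.precursor_mode is PrecursorMode.POS else mz + PROTON_MASS
            if best is None or neutral > best:
                best = neutral
    if best is None:
        raise ValueError("no peaks available to estimate the molecular weight")
    return best


def recommend(
    ae: SmilesAutoencoder,
    spec_encoder,
    tensor: ChannelTensor,
    index: EmbeddingIndex | None,
    reference_mw: float,
    query_id: str = "",
    n_samples: int = 100,
    k: int = 20,
    top_k: int = 20,
    seed: int = 0,
    strategy: str = "combined",
) -> CandidateSet:
    """Full recommendation pipeline for one spectra tensor.

    Encodes the tensor, generates candidates by the requested strategy
    (``direct``, ``indirect`` or ``combined``), deduplicates by canonical
    SMILES (indirect provenance wins on overlap), ranks ascending by
    ``|MW - reference_mw|`` — stable, ties broken indirect-first then
    lexicographically — and truncates to ``top_k``.
    """
    if reference_mw <= 0:
        raise ValueError("reference_mw must be positive")
    if strategy not in ("direct", "indirect", "combined"):
        raise ValueError(f"unknown strategy {strategy!r}")
    emb = spec_encoder.encode_tensor(tensor)

    pool: dict[str, Candidate] = {}
    if strategy in ("indirect", "combined") and index is not None:
        for mol in indirect_generate(index, emb, k=k, ae=ae):
            pool[mol.canonical_smiles] = Candidate(
                molecule=mol,
                source=CandidateSource.INDIRECT,
                mw_discrepancy=abs(mol.mol_weight - reference_mw),
            )
    if strategy in ("direct", "combined"):
        for mol in direct_generate(ae, emb, n_samples=n_samples, seed=seed):
            pool.setdefault(
                mol.canonical_smiles,
                Candidate(
                    molecule=mol,
                    source=CandidateSource.DIRECT,
                    mw_discrepancy=abs(mol.mol_weight - reference_mw),
                ),
            )
    if not pool:
        logger.warning("no candidates generated for query %s", query_id or "<unnamed>")
    ranked = sorted(
        pool.values(),
        key=lambda c: (
            c.mw_discrepancy,
            0 if c.source is CandidateSource.INDIRECT else 1,
            c.molecule.canonical_smiles,
        ),
    )
    return CandidateSet(
        query_id=query_id, reference_mw=reference_mw, candidates=ranked[:top_k]
    )
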