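"""Spectra records, MSP/MGF parsing and the binned four-channel model input.

A molecule's measurement is up to four MS/MS spectra: {[M+H]+, [M-H]-}
precursors x {low 35% NCE, high 130% NCE} collision energies. Each spectrum
becomes a binned, max-normalized intensity vector; the four vectors stack
into one 4 x L channel tensor (missing spectra are all-zero channels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from math import ceil, floor
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PrecursorMode",
    "EnergyLevel",
    "SpectrumRecord",
    "ChannelTensor",
    "CHANNEL_ORDER",
    "bin_spectrum",
    "normalize_intensities",
    "assemble_channels",
    "read_msp",
    "read_mgf",
    "write_msp",
]

PROTON_MASS = 1.00728  # Da, charge carrier for [M+H]+ / [M-H]-

LOW_NCE = 35.0
HIGH_NCE = 130.0


class PrecursorMode(str, Enum):
    POS = "[M+H]+"
    NEG = "[M-H]-"


class EnergyLevel(str, Enum):
    LOW = "low"
    HIGH = "high"


#: Fixed channel slot order for the encoder input.
CHANNEL_ORDER: tuple[tuple[PrecursorMode, EnergyLevel], ...] = (
    (PrecursorMode.POS, EnergyLevel.LOW),
    (PrecursorMode.POS, EnergyLevel.HIGH),
    (PrecursorMode.NEG, EnergyLevel.LOW),
    (PrecursorMode.NEG, EnergyLevel.HIGH),
)


@dataclass
class SpectrumRecord:
    """One centroided MS/MS spectrum with acquisition metadata.

    ``peaks`` is a list of ``(mz, intensity)`` sorted ascending by m/z; an
    empty list represents a missing spectrum.
    """

    peaks: list[tuple[float, float]]
    precursor_mode: PrecursorMode
    energy_level: EnergyLevel
    nce: float
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("negative peak intensity")

    @property
    def is_empty(self) -> bool:
        return len(self.peaks) == 0


@dataclass
class ChannelTensor:
    """4 x L max-normalized binned intensities, fixed channel order."""

    values: np.ndarray
    bin_width: float
    max_mz: float
    channel_order: tuple = CHANNEL_ORDER

    def __post_init__(self) -> None:
        L = ceil(self.max_mz / self.bin_width)
        if self.values.shape != (4, L):
            raise ValueError(f"expected shape (4, {L}), got {self.values.shape}")


def bin_spectrum(
    spec: SpectrumRecord, bin_width: float = 1.0, max_mz: float = 500.0
) -> np.ndarray:
    """Accumulate peak intensities into left-closed bins floor(m/z / width).

    Peaks at or beyond ``max_mz`` are dropped with a warning; multiple peaks
    falling into one bin sum. An empty spectrum gives an all-zero vector.
    """
    if bin_width <= 0 or max_mz <= 0:
        raise ValueError("bin_width and max_mz must be positive")
    n_bins = ceil(max_mz / bin_width)
    vec = np.zeros(n_bins)
    n_dropped = 0
    for mz, intensity in spec.peaks:
        if intensity < 0:
            raise ValueError(f"negative intensity {intensity} at m/z {mz}")
        if mz >= max_mz:
            n_dropped += 1
            continue
        vec[floor(mz / bin_width)] += intensity
    if n_dropped:
        logger.warning(
            "dropped %d peak(s) with m/z >= %.3f (molecule %s)",
            n_dropped,
            max_mz,
            spec.molecule_id or "<unnamed>",
        )
    return vec


def normalize_intensities(vec: np.ndarray) -> np.ndarray:
    """Scale so the maximum bin equals 1.0; all-zero input passes through."""
    vec = np.asarray(vec, dtype=float)
    peak = vec.max(initial=0.0)
    if peak <= 0:
        return vec.copy()
    return vec / peak


def assemble_channels(
    records: list[SpectrumRecord],
    bin_width: float = 1.0,
    max_mz: float = 500.0,
) -> ChannelTensor:
    """Stack up to four spectra into their fixed channel slots.

    Order of ``records`` is irrelevant; each (precursor, energy) pair may
    appear at most once. Missing slots stay all-zero, mirroring how absent
    spectra enter the encoder.
    """
    n_bins = ceil(max_mz / bin_width)
    values = np.zeros((4, n_bins))
    seen: set[tuple[PrecursorMode, EnergyLevel]] = set()
    slot = {pair: i for i, pair in enumerate(CHANNEL_ORDER)}
    for rec in records:
        key = (rec.precursor_mode, rec.energy_level)
        if key in seen:
            raise ValueError(f"duplicate spectrum for channel {key}")
        seen.add(key)
        values[slot[key]] = normalize_intensities(
            bin_spectrum(rec, bin_width, max_mz)
        )
    return ChannelTensor(values=values, bin_width=bin_width, max_mz=max_mz)


# ---------------------------------------------------------------------------
# File formats. MSP (NIST dialect) is the native library format here; MGF is
# accepted as the common interchange format. Both go through matchms.

_MODE_BY_ADDUCT = {m.value: m for m in PrecursorMode}


def _quiet_rdkit() -> None:
    # matchms re-enables RDKit's C++ logging on import; keep it off so
    # expected parse failures (e.g. invalid sampled SMILES) stay silent
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")


def _energy_from_nce(nce: float) -> EnergyLevel:
    return EnergyLevel.LOW if nce < 100.0 else EnergyLevel.HIGH


def _record_from_matchms(spectrum, origin: str) -> SpectrumRecord | None:
    meta = spectrum.metadata
    adduct = meta.get("adduct") or meta.get("precursor_type") or meta.get("precursortype")
    if adduct not in _MODE_BY_ADDUCT:
        logger.warning("skipping spectrum with unsupported precursor type %r in %s", adduct, origin)
        return None
    nce_raw = meta.get("nce")
    if nce_raw is None:
        logger.warning("skipping spectrum without NCE annotation in %s", origin)
        return None
    nce = float(nce_raw)
    name = meta.get("compound_name") or meta.get("name") or meta.get("title") or ""
    peaks = list(zip(spectrum.peaks.mz.tolist(), spectrum.peaks.intensities.tolist()))
    return SpectrumRecord(
        peaks=peaks,
        precursor_mode=_MODE_BY_ADDUCT[adduct],
        energy_level=_energy_from_nce(nce),
        nce=nce,
        molecule_id=str(name),
    )


def read_msp(path: str | Path) -> list[SpectrumRecord]:
    """Read an MSP library; unsupported precursor types are skipped with a warning."""
    from matchms.importing import load_from_msp

    _quiet_rdkit()
    records = []
    for spectrum in load_from_msp(str(path), metadata_harmonization=False):
        rec = _record_from_matchms(spectrum, str(path))
        if rec is not None:
            records.append(rec)
    return records


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF file (BEGIN IONS blocks with NCE= and ADDUCT= headers)."""
    from matchms.importing import load_from_mgf

    _quiet_rdkit()
    records = []
    for spectrum in load_from_mgf(str(path), metadata_harmonization=False):
        rec = _record_from_matchms(spectrum, str(path))
        if rec is not None:
            records.append(rec)
    return records


def write_msp(records: list[SpectrumRecord], path: str | Path) -> None:
    """Write records as MSP; round-trips peaks and the metadata this package uses."""
    from matchms import Spectrum
    from matchms.exporting import save_as_msp

    _quiet_rdkit()
    path = Path(path)
    if path.exists():
        path.unlink()  # matchms appends to existing files
    spectra = []
    for rec in records:
        mz = np.array([m for m, _ in rec.peaks], dtype=float)
        intensities = np.array([i for _, i in rec.peaks], dtype=float)
        spectra.append(
            Spectrum(
                mz=mz,
                intensities=intensities,
                metadata={
                    "compound_name": rec.molecule_id,
                    "precursor_type": rec.precursor_mode.value,
                    "nce": f"{rec.nce:g}",
                },
                metadata_harmonization=False,
            )
        )
    save_as_msp(spectra, str(path))
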