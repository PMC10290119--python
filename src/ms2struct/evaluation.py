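"""Molecular-similarity evaluation of recommended structures.

Candidate sets are compared against their reference molecules at three
levels: physicochemical (molecular weight, molecular formula, per-element
presence), fingerprint (Morgan radius-2/1024-bit cosine), and substructure
(maximum common substructure under strict matching: same element, same bond
order, ring bonds only onto ring bonds). Aggregates follow the dataset-wide
relative definitions:

    DMW_min = mean_cases(min_cand |MW_c - MW_ref|) / mean_cases(MW_ref) * 100
    DMF_min = mean_cases(min_cand d_formula)       / mean_cases(n_heavy_ref) * 100

(and analogously with per-case means for the *_avg variants), where
d_formula is the heavy-atom-only L1 distance between element-count maps.
The three MCS ratios over atom counts a_mcs, a_ref, a_pred are

    MCS_ratio = a_mcs / a_ref
    MCS_tan   = a_mcs / (a_ref + a_pred - a_mcs)
    MCS_ovrlp = a_mcs / min(a_ref, a_pred)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem import Molecule, morgan_fingerprint

logger = logging.getLogger(__name__)

__all__ = [
    "McsResult",
    "EvalReport",
    "formula_distance",
    "dmw_aggregate",
    "dmf_aggregate",
    "element_detection",
    "fingerprint_cosine",
    "mcs_metrics",
    "evaluate",
    "DEFAULT_ELEMENTS",
]

#: Heteroatoms tracked by element-presence detection. Carbon is excluded:
#: it is present in every molecule, so its detection is uninformative.
DEFAULT_ELEMENTS = ("O", "N", "S", "Cl", "F", "Br", "P", "I")


def formula_distance(f1: dict[str, int], f2: dict[str, int]) -> int:
    """Heavy-atom formula distance: sum over non-H elements of |n1 - n2|."""
    elements = (set(f1) | set(f2)) - {"H"}
    return sum(abs(f1.get(e, 0) - f2.get(e, 0)) for e in elements)


def dmw_aggregate(
    cases: list[tuple[float, list[float]]]
) -> tuple[float, float]:
    """Relative molecular-weight discrepancy over a case set, in percent.

    Each case is ``(reference_mw, [candidate_mw, ...])``. Cases with no
    candidates are excluded with a warning.
    """
    mins, avgs, refs = [], [], []
    n_skipped = 0
    for ref_mw, cand_mws in cases:
        if not cand_mws:
            n_skipped += 1
            continue
        diffs = [abs(c - ref_mw) for c in cand_mws]
        mins.append(min(diffs))
        avgs.append(float(np.mean(diffs)))
        refs.append(ref_mw)
    if n_skipped:
        logger.warning("dmw_aggregate: excluded %d case(s) with no candidates", n_skipped)
    if not refs:
        raise ValueError("no cases with candidates")
    denom = float(np.mean(refs))
    return 100.0 * float(np.mean(mins)) / denom, 100.0 * float(np.mean(avgs)) / denom


def dmf_aggregate(
    cases: list[tuple[dict[str, int], list[dict[str, int]]]]
) -> tuple[float, float]:
    """Relative molecular-formula discrepancy, in percent.

    Each case is ``(reference_formula, [candidate_formula, ...])``; the
    denominator is the mean reference heavy-atom count.
    """
    mins, avgs, heavies = [], [], []
    n_skipped = 0
    for ref_formula, cand_formulas in cases:
        if not cand_formulas:
            n_skipped += 1
            continue
        dists = [formula_distance(ref_formula, c) for c in cand_formulas]
        mins.append(min(dists))
        avgs.append(float(np.mean(dists)))
        heavies.append(sum(v for k, v in ref_formula.items() if k != "H"))
    if n_skipped:
        logger.warning("dmf_aggregate: excluded %d case(s) with no candidates", n_skipped)
    if not heavies:
        raise ValueError("no cases with candidates")
    denom = float(np.mean(heavies))
    return 100.0 * float(np.mean(mins)) / denom, 100.0 * float(np.mean(avgs)) / denom


def element_detection(
    cases: list[tuple[dict[str, int], list[dict[str, int]]]],
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> dict[str, dict[str, float | None]]:
    """Per-element presence sensitivity/specificity across cases.

    An element counts as predicted present if it appears in any candidate;
    atom counts are ignored. Ratios with an empty denominator are reported
    as ``None`` (not available), never as zero.
    """
    result: dict[str, dict[str, float | None]] = {}
    for element in elements:
        tp = fn = tn = fp = 0
        for ref_formula, cand_formulas in cases:
            in_ref = ref_formula.get(element, 0) > 0
            in_pred = any(c.get(element, 0) > 0 for c in cand_formulas)
            if in_ref and in_pred:
                tp += 1
            elif in_ref:
                fn += 1
            elif in_pred:
                fp += 1
            else:
                tn += 1
        result[element] = {
            "sensitivity": tp / (tp + fn) if (tp + fn) else None,
            "specificity": tn / (tn + fp) if (tn + fp) else None,
        }
    return result


def fingerprint_cosine(ref: Molecule | str, pred: Molecule | str) -> float:
    """Cosine of Morgan (radius 2, 1024-bit) fingerprints: |A&B|/sqrt(|A||B|)."""
    ref_s = ref.canonical_smiles if isinstance(ref, Molecule) else ref
    pred_s = pred.canonical_smiles if isinstance(pred, Molecule) else pred
    a = set(morgan_fingerprint(ref_s).GetOnBits())
    b = set(morgan_fingerprint(pred_s).GetOnBits())
    if not a or not b:
        return 0.0
    return len(a & b) / np.sqrt(len(a) * len(b))


@dataclass(frozen=True)
class McsResult:
    """Atom counts of a maximum-common-substructure comparison."""

    a_mcs: int
    a_r: int
    a_p: int

    def __post_init__(self) -> None:
        if not 0 <= self.a_mcs <= min(self.a_r, self.a_p):
            raise ValueError("inconsistent MCS atom counts")


def mcs_metrics(
    ref: Molecule | str, pred: Molecule | str, timeout_s: int = 10
) -> tuple[McsResult, float, float, float]:
    """Constrained MCS and its three atom-count ratios.

    The match respects element identity and exact bond order, and ring
    bonds match only ring bonds; the common substructure is connected. A
    substructure must contain at least one bond — if the two molecules
    share no matchable bond, ``a_mcs`` is 0 and all ratios are 0. The
    search is time-capped; on timeout the best substructure found so far is
    used and a warning logged.
    """
    ref_s = ref.canonical_smiles if isinstance(ref, Molecule) else ref
    pred_s = pred.canonical_smiles if isinstance(pred, Molecule) else pred
    m_ref = Chem.MolFromSmiles(ref_s)
    m_pred = Chem.MolFromSmiles(pred_s)
    a_r, a_p = m_ref.GetNumAtoms(), m_pred.GetNumAtoms()
    res = rdFMCS.FindMCS(
        [m_ref, m_pred],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrderExact,
        ringMatchesRingOnly=True,
        timeout=timeout_s,
    )
    if res.canceled:
        logger.warning(
            "MCS search timed out after %ds for %s vs %s; using best-so-far",
            timeout_s,
            ref_s,
            pred_s,
        )
    a_mcs = res.numAtoms if res.numBonds > 0 else 0
    result = McsResult(a_mcs=max(a_mcs, 0), a_r=a_r, a_p=a_p)
    if result.a_mcs == 0:
        return result, 0.0, 0.0, 0.0
    ratio = result.a_mcs / a_r
    tan = result.a_mcs / (a_r + a_p - result.a_mcs)
    ovrlp = result.a_mcs / min(a_r, a_p)
    return result, ratio, tan, ovrlp


@dataclass
class EvalReport:
    """Per-case table plus recomputable dataset aggregates."""

    per_case: pd.DataFrame
    aggregate: dict
    strata: dict[str, dict] = field(default_factory=dict)


_PER_CASE_COLUMNS = [
    "case_id", "n_candidates",
    "min_mw_diff", "avg_mw_diff",
    "min_formula_dist", "avg_formula_dist",
    "max_fp_cosine", "avg_fp_cosine",
    "max_mcs_ratio", "avg_mcs_ratio",
    "max_mcs_tan", "avg_mcs_tan",
    "max_mcs_ovrlp", "avg_mcs_ovrlp",
    "exact_structure", "exact_formula",
]


def _aggregate_rows(
    rows: pd.DataFrame,
    formula_cases: list,
    mw_cases: list,
    elements: tuple[str, ...],
) -> dict:
    dmw_min, dmw_avg = dmw_aggregate(mw_cases)
    dmf_min, dmf_avg = dmf_aggregate(formula_cases)
    return {
        "n_cases": int(len(rows)),
        "correct_molecules_pct": 100.0 * float(rows["exact_structure"].mean()),
        "correct_formulas_pct": 100.0 * float(rows["exact_formula"].mean()),
        "dmw_min_pct": dmw_min,
        "dmw_avg_pct": dmw_avg,
        "dmf_min_pct": dmf_min,
        "dmf_avg_pct": dmf_avg,
        "fp_cosine_max": float(rows["max_fp_cosine"].mean()),
        "fp_cosine_avg": float(rows["avg_fp_cosine"].mean()),
        "mcs_ratio_max": float(rows["max_mcs_ratio"].mean()),
        "mcs_ratio_avg": float(rows["avg_mcs_ratio"].mean()),
        "mcs_tan_max": float(rows["max_mcs_tan"].mean()),
        "mcs_tan_avg": float(rows["avg_mcs_tan"].mean()),
        "mcs_ovrlp_max": float(rows["max_mcs_ovrlp"].mean()),
        "mcs_ovrlp_avg": float(rows["avg_mcs_ovrlp"].mean()),
        "element_detection": element_detection(formula_cases, elements),
    }


def evaluate(
    cases: list[tuple[Molecule, "CandidateSet"]],
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
    strata: dict[str, str] | None = None,
    mcs_timeout_s: int = 10,
) -> EvalReport:
    """Score candidate sets against their references.

    ``cases`` pairs each reference molecule with its
    :class:`~ms2struct.generation.CandidateSet` (case ids must be unique).
    ``strata`` optionally maps case id to a stratum label (e.g. number of
    available spectra, generation strategy, or MW class); per-stratum
    aggregates are then reported alongside the full-set aggregate.

    Exact-structure means some candidate has the same canonical SMILES as
    the reference; exact-formula compares full element-count maps including
    hydrogens. Cases with an empty candidate set stay in the per-case table
    but are excluded (with a warning) from the relative aggregates.
    """
    if not cases:
        raise ValueError("empty case list")
    ids = [cs.query_id for _, cs in cases]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate case ids: {dupes}")

    rows = []
    mw_cases, formula_cases = [], []
    for ref, cand_set in cases:
        cands = [c.molecule for c in cand_set.candidates]
        mw_cases.append((ref.mol_weight, [c.mol_weight for c in cands]))
        formula_cases.append((ref.formula, [c.formula for c in cands]))
        if not cands:
            rows.append(
                dict.fromkeys(_PER_CASE_COLUMNS, np.nan)
                | {"case_id": cand_set.query_id, "n_candidates": 0,
                   "exact_structure": False, "exact_formula": False}
            )
            continue
        mw_diffs = [abs(c.mol_weight - ref.mol_weight) for c in cands]
        f_dists = [formula_distance(ref.formula, c.formula) for c in cands]
        cosines = [fingerprint_cosine(ref, c) for c in cands]
        mcs_rows = [mcs_metrics(ref, c, timeout_s=mcs_timeout_s) for c in cands]
        ratios = [r for _, r, _, _ in mcs_rows]
        tans = [t for _, _, t, _ in mcs_rows]
        ovrlps = [o for _, _, _, o in mcs_rows]
        rows.append(
            {
                "case_id": cand_set.query_id,
                "n_candidates": len(cands),
                "min_mw_diff": min(mw_diffs),
                "avg_mw_diff": float(np.mean(mw_diffs)),
                "min_formula_dist": min(f_dists),
                "avg_formula_dist": float(np.mean(f_dists)),
                "max_fp_cosine": max(cosines),
                "avg_fp_cosine": float(np.mean(cosines)),
                "max_mcs_ratio": max(ratios),
                "avg_mcs_ratio": float(np.mean(ratios)),
                "max_mcs_tan": max(tans),
                "avg_mcs_tan": float(np.mean(tans)),
                "max_mcs_ovrlp": max(ovrlps),
                "avg_mcs_ovrlp": float(np.mean(ovrlps)),
                "exact_structure": any(
                    c.canonical_smiles == ref.canonical_smiles for c in cands
                ),
                "exact_formula": any(c.formula == ref.formula for c in cands),
            }
        )
    per_case = pd.DataFrame(rows, columns=_PER_CASE_COLUMNS)
    scored = per_case[per_case["n_candidates"] > 0]
    aggregate = _aggregate_rows(
        scored,
        [f for f, r in zip(formula_cases, rows) if r["n_candidates"] > 0],
        [m for m, r in zip(mw_cases, rows) if r["n_candidates"] > 0],
        elements,
    )

    strata_out: dict[str, dict] = {}
    if strata is not None:
        labels = sorted({strata[i] for i in ids if i in strata})
        for label in labels:
            keep = [
                (r["n_candidates"] > 0) and strata.get(r["case_id"]) == label
                for r in rows
            ]
            sub_rows = per_case[keep]
            if sub_rows.empty:
                continue
            strata_out[label] = _aggregate_rows(
                sub_rows,
                [f for f, k in zip(formula_cases, keep) if k],
                [m for m, k in zip(mw_cases, keep) if k],
                elements,
            )
    return EvalReport(per_case=per_case, aggregate=aggregate, strata=strata_out)
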