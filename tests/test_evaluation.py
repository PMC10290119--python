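import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ms2struct.chem import Molecule, morgan_fingerprint
from ms2struct.evaluation import (
    McsResult,
    dmf_aggregate,
    dmw_aggregate,
    element_detection,
    evaluate,
    fingerprint_cosine,
    formula_distance,
    mcs_metrics,
)
from ms2struct.generation import Candidate, CandidateSet, CandidateSource

from .oracles import brute_force_mcs_atoms, cosine_from_bitsets

# Panel for oracle equivalence: small molecules (<= 8 heavy atoms) spanning
# chains, rings, aromatics, heteroatoms, halogens and multiple bond orders.
PANEL = [
    "CCO", "CCCO", "CCCCO", "CCN", "CCS", "CC(C)O", "CC(C)C", "CC(N)C(=O)O",
    "CC(=O)O", "CC(=O)C", "CC=O", "C=CC", "C#CC", "CC#N", "ClCC", "BrCCO",
    "FC(F)C", "OCC(O)CO", "CCOC", "CCOCC", "c1ccccc1", "c1ccncc1", "c1ccoc1",
    "c1ccsc1", "c1cc[nH]c1", "C1CCCCC1", "C1CCCC1", "C1CC1", "C1CCOC1", "C1CCNC1",
]


class TestFormulaDistance:
    def test_benzene_vs_pyridine(self):
        assert formula_distance({"C": 6, "H": 6}, {"C": 5, "H": 5, "N": 1}) == 2

    def test_identical_zero(self):
        assert formula_distance({"C": 2, "H": 6, "O": 1}, {"C": 2, "H": 6, "O": 1}) == 0

    def test_hydrogen_excluded(self):
        assert formula_distance({"C": 2, "H": 6, "O": 1}, {"C": 2, "H": 4, "O": 1}) == 0

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["C", "N", "O", "S", "Cl"]), st.integers(0, 9)
            ),
            min_size=0, max_size=5,
        ).map(dict),
        st.lists(
            st.tuples(
                st.sampled_from(["C", "N", "O", "S", "Cl"]), st.integers(0, 9)
            ),
            min_size=0, max_size=5,
        ).map(dict),
        st.lists(
            st.tuples(
                st.sampled_from(["C", "N", "O", "S", "Cl"]), st.integers(0, 9)
            ),
            min_size=0, max_size=5,
        ).map(dict),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, f1, f2, f3):
        assert formula_distance(f1, f1) == 0
        assert formula_distance(f1, f2) == formula_distance(f2, f1)
        assert formula_distance(f1, f3) <= formula_distance(f1, f2) + formula_distance(f2, f3)


class TestAggregates:
    def test_dmw_perfect(self):
        assert dmw_aggregate([(100.0, [100.0]), (50.0, [50.0])]) == (0.0, 0.0)

    def test_dmw_worked_example(self):
        dmw_min, dmw_avg = dmw_aggregate([(100.0, [90.0, 120.0])])
        assert dmw_min == pytest.approx(10.0)
        assert dmw_avg == pytest.approx(15.0)

    def test_dmw_sign_invariant(self):
        up = dmw_aggregate([(100.0, [110.0]), (100.0, [105.0])])
        down = dmw_aggregate([(100.0, [90.0]), (100.0, [95.0])])
        assert up == down

    def test_dmf_worked_example(self):
        # reference C6 (6 heavy atoms); candidates C6 and C5N
        dmf_min, dmf_avg = dmf_aggregate([({"C": 6}, [{"C": 6}, {"C": 5, "N": 1}])])
        assert dmf_min == pytest.approx(0.0)
        assert dmf_avg == pytest.approx(100.0 / 6, abs=0.01)

    def test_dmf_candidate_order_invariant(self):
        case = ({"C": 6}, [{"C": 5, "N": 1}, {"C": 6}])
        assert dmf_aggregate([case]) == dmf_aggregate(
            [(case[0], list(reversed(case[1])))]
        )

    def test_empty_case_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = dmw_aggregate([(100.0, [100.0]), (50.0, [])])
        assert out == (0.0, 0.0)
        assert "excluded 1" in caplog.text


class TestElementDetection:
    def test_perfect_predictions(self):
        cases = [
            ({"C": 2, "N": 1}, [{"C": 2, "N": 1}]),
            ({"C": 3, "O": 1}, [{"C": 3, "O": 1}]),
        ]
        out = element_detection(cases)
        assert out["N"]["sensitivity"] == 1.0 and out["N"]["specificity"] == 1.0
        assert out["O"]["sensitivity"] == 1.0 and out["O"]["specificity"] == 1.0

    def test_absent_element_sensitivity_not_available(self):
        cases = [({"C": 1}, [{"C": 1}])]
        out = element_detection(cases)
        assert out["S"]["sensitivity"] is None
        assert out["S"]["specificity"] == 1.0

    def test_hand_confusion_matrix(self):
        # N: 2 TP, 1 FN, 1 TN -> sensitivity 2/3, specificity 1.0
        cases = [
            ({"N": 1}, [{"N": 1}]),
            ({"N": 2}, [{"N": 1}]),
            ({"N": 1}, [{"C": 1}]),
            ({"C": 1}, [{"C": 1}]),
        ]
        out = element_detection(cases)
        assert out["N"]["sensitivity"] == pytest.approx(2 / 3, abs=1e-3)
        assert out["N"]["specificity"] == 1.0


class TestFingerprintCosine:
    def test_identity(self):
        assert fingerprint_cosine("CCO", "CCO") == pytest.approx(1.0)

    def test_symmetry(self):
        assert fingerprint_cosine("CCO", "CCCO") == pytest.approx(
            fingerprint_cosine("CCCO", "CCO")
        )

    def test_matches_bitset_oracle(self):
        for a, b in itertools.combinations(PANEL[:12], 2):
            expected = cosine_from_bitsets(
                set(morgan_fingerprint(a).GetOnBits()),
                set(morgan_fingerprint(b).GetOnBits()),
            )
            assert fingerprint_cosine(a, b) == pytest.approx(expected, abs=1e-12)


class TestMcs:
    def test_identity_all_ones(self):
        res, ratio, tan, ovrlp = mcs_metrics("CCO", "CCO")
        assert (res.a_mcs, res.a_r, res.a_p) == (3, 3, 3)
        assert (ratio, tan, ovrlp) == (1.0, 1.0, 1.0)

    def test_ethanol_propanol_worked_example(self):
        res, ratio, tan, ovrlp = mcs_metrics("CCO", "CCCO")
        assert res.a_mcs == 3
        assert ratio == pytest.approx(1.0)
        assert tan == pytest.approx(0.75)
        assert ovrlp == pytest.approx(1.0)

    def test_benzene_cyclohexane_no_common_bond(self):
        res, ratio, tan, ovrlp = mcs_metrics("c1ccccc1", "C1CCCCC1")
        assert res.a_mcs == 0
        assert (ratio, tan, ovrlp) == (0.0, 0.0, 0.0)

    def test_mcs_result_bounds_validated(self):
        with pytest.raises(ValueError):
            McsResult(a_mcs=5, a_r=3, a_p=4)

    def test_tan_is_smallest_metric(self):
        for a, b in itertools.combinations(PANEL[:15], 2):
            _, ratio, tan, ovrlp = mcs_metrics(a, b)
            assert tan <= ratio + 1e-12
            assert tan <= ovrlp + 1e-12


def _candidate_set(query_id, ref, smiles_list, source=CandidateSource.DIRECT):
    cands = [
        Candidate(
            molecule=Molecule.from_smiles(s),
            source=source,
            mw_discrepancy=abs(Molecule.from_smiles(s).mol_weight - ref.mol_weight),
        )
        for s in smiles_list
    ]
    return CandidateSet(query_id=query_id, reference_mw=ref.mol_weight, candidates=cands)


class TestEvaluate:
    def test_self_candidates_perfect(self):
        refs = [Molecule.from_smiles(s) for s in ("CCO", "c1ccccc1", "CC(=O)O")]
        cases = [(r, _candidate_set(f"q{i}", r, [r.canonical_smiles])) for i, r in enumerate(refs)]
        report = evaluate(cases)
        agg = report.aggregate
        assert agg["correct_molecules_pct"] == 100.0
        assert agg["correct_formulas_pct"] == 100.0
        assert agg["mcs_tan_max"] == 1.0
        assert agg["fp_cosine_max"] == 1.0
        assert agg["dmw_min_pct"] == 0.0

    def test_aggregates_recomputable_from_per_case(self):
        refs = [Molecule.from_smiles(s) for s in ("CCO", "CCCO", "CCN")]
        cases = [
            (refs[0], _candidate_set("a", refs[0], ["CCO", "CCCCO"])),
            (refs[1], _candidate_set("b", refs[1], ["CCN"])),
            (refs[2], _candidate_set("c", refs[2], ["CCO", "CCC"])),
        ]
        report = evaluate(cases)
        table = report.per_case
        assert report.aggregate["correct_molecules_pct"] == pytest.approx(
            100.0 * table["exact_structure"].mean()
        )
        assert report.aggregate["fp_cosine_max"] == pytest.approx(
            table["max_fp_cosine"].mean()
        )
        # DMW re-derivation from per-case rows
        expected_dmw_min = (
            100.0 * table["min_mw_diff"].mean() / np.mean([r.mol_weight for r in refs])
        )
        assert report.aggregate["dmw_min_pct"] == pytest.approx(expected_dmw_min)

    def test_duplicate_case_ids_rejected(self):
        ref = Molecule.from_smiles("CCO")
        cases = [
            (ref, _candidate_set("dup", ref, ["CCO"])),
            (ref, _candidate_set("dup", ref, ["CCN"])),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            evaluate(cases)

    def test_strata_partition_case_set(self):
        refs = [Molecule.from_smiles(s) for s in ("CCO", "CCCO", "CCN", "CCS")]
        cases = [
            (r, _candidate_set(f"q{i}", r, [r.canonical_smiles])) for i, r in enumerate(refs)
        ]
        strata = {"q0": "small", "q1": "small", "q2": "large", "q3": "large"}
        report = evaluate(cases, strata=strata)
        assert set(report.strata) == {"small", "large"}
        assert sum(s["n_cases"] for s in report.strata.values()) == len(cases)

    def test_exact_formula_includes_hydrogens(self):
        ref = Molecule.from_smiles("CCO")  # C2H6O
        # C2H4O: same heavy atoms, fewer hydrogens -> formula distance 0 but not exact
        report = evaluate([(ref, _candidate_set("q", ref, ["CC=O"]))])
        row = report.per_case.iloc[0]
        assert row["min_formula_dist"] == 0
        assert not row["exact_formula"]


class TestMcsOracleEquivalence:
    """Production MCS vs brute-force maximum common connected subgraph."""

    @pytest.mark.parametrize(
        "pair",
        list(itertools.combinations(PANEL[:14], 2)),
        ids=lambda p: f"{p[0]}|{p[1]}",
    )
    def test_matches_brute_force(self, pair):
        a, b = pair
        res, _, _, _ = mcs_metrics(a, b)
        assert res.a_mcs == brute_force_mcs_atoms(a, b)
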