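"""Ligand assignment, functional pairs, scoring and stratification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirmod import kir_core
from kirmod.kir_core import (
    A3A11,
    BW4_80I,
    BW4_80T,
    C1,
    C2,
    LigandProfile,
    ScoreWeights,
    assign_ligands,
    functional_pairs,
    ikir_score,
    stratify,
)


class TestAssignLigands:
    def test_b5701_is_bw4_80i(self):
        assert assign_ligands(["B*57:01"]).bw4 == BW4_80I

    def test_a2402_is_bw4_80i(self):
        assert assign_ligands(["A*24:02"]).bw4 == BW4_80I

    def test_c1_homozygote_without_bw4(self):
        prof = assign_ligands(["C*07:01", "C*07:02"])
        assert prof.bw4 == "absent" and prof.c1 and not prof.c2

    def test_c_heterozygote_sets_both_groups(self):
        prof = assign_ligands(["C*07:01", "C*04:01"])
        assert prof.c1 and prof.c2

    def test_b27_subtype_split_uses_most_specific_prefix(self):
        assert assign_ligands(["B*27:05"]).bw4 == BW4_80T
        assert assign_ligands(["B*27:02"]).bw4 == BW4_80I

    def test_80i_dominates_80t(self):
        assert assign_ligands(["B*57:01", "B*44:02"]).bw4 == BW4_80I

    def test_a3_a11_ligand(self):
        assert assign_ligands(["A*03:01"]).a3a11

    def test_unknown_hla_c_allele_policy(self):
        with pytest.raises(kir_core.LigandTableError):
            assign_ligands(["C*99:99"])
        prof = assign_ligands(["C*99:99"], unknown="ignore")
        assert not prof.c1 and not prof.c2

    def test_non_ligand_b_allele_is_fine(self):
        assert assign_ligands(["B*07:02"]).bw4 == "absent"


# independent brute-force rule table for functional pairs
_RULES = {
    "KIR2DL1": lambda p: [("KIR2DL1", C2)] if p.c2 else [],
    "KIR2DL2": lambda p: [("KIR2DL2", C1)] if p.c1 else [],
    "KIR2DL3": lambda p: [("KIR2DL3", C1)] if p.c1 else [],
    "KIR3DL1": lambda p: [("KIR3DL1", p.bw4)] if p.bw4 != "absent" else [],
}


class TestFunctionalPairs:
    def test_gene_without_ligand(self):
        assert functional_pairs({"KIR2DL1"}, LigandProfile(c2=False)) == set()

    def test_gene_with_ligand(self):
        assert functional_pairs({"KIR2DL1"}, LigandProfile(c2=True)) == {
            ("KIR2DL1", C2)
        }

    def test_both_pairs_present(self):
        prof = LigandProfile(bw4=BW4_80I, c1=True)
        got = functional_pairs({"KIR3DL1", "KIR2DL3"}, prof)
        assert got == {("KIR3DL1", BW4_80I), ("KIR2DL3", C1)}

    @pytest.mark.parametrize("bw4", ["absent", BW4_80I, BW4_80T])
    @pytest.mark.parametrize("c1", [False, True])
    @pytest.mark.parametrize("c2", [False, True])
    def test_against_rule_table(self, bw4, c1, c2):
        prof = LigandProfile(bw4=bw4, c1=c1, c2=c2)
        for genes in itertools.chain.from_iterable(
            itertools.combinations(_RULES, k) for k in range(len(_RULES) + 1)
        ):
            expected = {
                pair for g in genes for pair in _RULES[g](prof)
            }
            assert functional_pairs(set(genes), prof) == expected

    def test_kir3dl2_membership_is_configurable(self):
        prof = LigandProfile(a3a11=True)
        assert functional_pairs({"KIR3DL2"}, prof) == set()
        assert functional_pairs({"KIR3DL2"}, prof, include_kir3dl2=True) == {
            ("KIR3DL2", A3A11)
        }


class TestScore:
    def test_empty_pairs_score_zero(self):
        assert ikir_score(set()) == 0.0

    def test_unit_weights_reduce_to_count(self):
        w = ScoreWeights.default().unit()
        pairs = {("KIR2DL1", C2), ("KIR2DL3", C1), ("KIR3DL1", BW4_80I)}
        assert ikir_score(pairs, w) == 3.0

    def test_hand_sum_at_threshold(self):
        w = ScoreWeights(weights={"KIR2DL1/C2": 1.0, "KIR3DL1/Bw4-80T": 0.75})
        pairs = {("KIR2DL1", C2), ("KIR3DL1", BW4_80T)}
        assert ikir_score(pairs, w) == pytest.approx(1.75)

    def test_missing_weight_is_configuration_error(self):
        w = ScoreWeights(weights={"KIR2DL1/C2": 1.0})
        with pytest.raises(kir_core.WeightError):
            ikir_score({("KIR2DL3", C1)}, w)

    def test_attainable_range_contains_reference_thresholds(self):
        lo, hi = ScoreWeights.default().attainable_range()
        for thr in (1.5, 1.75, 2.0, 2.5):
            assert lo < thr < hi

    @settings(deadline=None, max_examples=60)
    @given(
        genes=st.sets(st.sampled_from(sorted(_RULES))),
        extra=st.sampled_from(sorted(_RULES)),
        bw4=st.sampled_from(["absent", BW4_80I, BW4_80T]),
        c1=st.booleans(),
        c2=st.booleans(),
    )
    def test_score_monotone_in_genes(self, genes, extra, bw4, c1, c2):
        """Adding a KIR gene never decreases the score."""
        prof = LigandProfile(bw4=bw4, c1=c1, c2=c2)
        w = ScoreWeights.default()
        s0 = ikir_score(functional_pairs(genes, prof), w)
        s1 = ikir_score(functional_pairs(genes | {extra}, prof), w)
        assert s1 >= s0

    def test_score_invariant_to_allele_order_and_homozygosity(self):
        genes = {"KIR2DL1", "KIR3DL1"}
        a = ["B*57:01", "C*04:01", "C*07:01"]
        s = lambda alleles: ikir_score(
            functional_pairs(genes, assign_ligands(alleles))
        )
        assert s(a) == s(list(reversed(a))) == s(a + ["B*57:01"])


class TestStratify:
    def test_tie_goes_low(self):
        assert stratify(1.75, 1.75) == "low"

    def test_above_threshold_is_high(self):
        assert stratify(1.76, 1.75) == "high"

    def test_zero_scores_low_for_any_positive_threshold(self):
        for thr in (0.5, 1.5, 2.5):
            assert stratify(0.0, thr) == "low"


def test_profile_individual_end_to_end():
    prof = kir_core.profile_individual(
        {"KIR2DL1", "KIR3DL1"},
        ["A*01:01", "A*24:02", "B*07:02", "B*07:02", "C*04:01", "C*05:01"],
    )
    # KIR2DL1/C2 (1.0) + KIR3DL1/Bw4-80I via A*24:02 (1.0)
    assert prof.score == pytest.approx(2.0)
    assert prof.stratum == "high"
    assert ("KIR3DL1", BW4_80I) in prof.functional_pairs
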