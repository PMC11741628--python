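"""Stratified transmission analysis: hand-counted fixtures, the log-ratio
difference statistic, and the score-permutation null."""

import math

import numpy as np
import pytest

from kirmod import family_tdt, syndata
from kirmod.family_tdt import (
    TransmissionTable,
    strata_difference_stat,
    tdt_permutation_test,
    transmission_counts,
)
from kirmod.syndata import IndividualRecord, TrioRecord

DQ6 = "DQA1*01:02-DQB1*06:02"
H_DQ6 = "DRB1*15:01|DQA1*01:02|DQB1*06:02"
H_NEU = "DRB1*01:01|DQA1*01:01|DQB1*05:01"
H_DR3 = "DRB1*03:01|DQA1*05:01|DQB1*02:01"


def _person(pid, hap1, hap2, sex="M", score=0.0):
    return IndividualRecord(
        id=pid, case_status="control", sex=sex, kir_genes=frozenset(),
        hla_class1=("", "", "", "", "", ""), hla_class2=("", "", "", "", "", ""),
        hap1=hap1, hap2=hap2, score=score,
    )


def _trio(fam, f_haps, m_haps, tf, tm, child_score):
    child = _person(f"{fam}_C", f_haps[tf], m_haps[tm], score=child_score)
    child.case_status = "case"
    return TrioRecord(
        family_id=fam,
        child=child,
        father=_person(f"{fam}_F", *f_haps),
        mother=_person(f"{fam}_M", *m_haps, sex="F"),
        transmitted_father=tf,
        transmitted_mother=tm,
    )


@pytest.fixture
def hand_trios():
    """Four hand-built trios with known transmissions of the DQ6 haplotype.

    Informative parents (heterozygous for the DQ6-bearing haplotype):
      trio 0 (child score 2.5, high): father transmits DQ6 (T)
      trio 1 (high): father does not transmit (NT), mother uninformative (hom)
      trio 2 (low): mother transmits (T), father uninformative (no DQ6)
      trio 3 (low): father NT, mother NT
    """
    return [
        _trio("f0", (H_DQ6, H_NEU), (H_NEU, H_DR3), 0, 1, 2.5),
        _trio("f1", (H_DQ6, H_NEU), (H_DQ6, H_DQ6), 1, 0, 2.0),
        _trio("f2", (H_NEU, H_DR3), (H_DQ6, H_NEU), 0, 0, 1.0),
        _trio("f3", (H_DQ6, H_NEU), (H_DQ6, H_DR3), 1, 1, 0.5),
    ]


class TestTransmissionCounts:
    def test_hand_counted_table(self, hand_trios):
        tab = transmission_counts(hand_trios, DQ6, threshold=1.75)
        assert (tab.t_high, tab.nt_high) == (1, 1)
        assert (tab.t_low, tab.nt_low) == (1, 2)
        assert tab.n_informative_parents == 5

    def test_homozygous_parent_uninformative(self, hand_trios):
        tab = transmission_counts(hand_trios, DQ6)
        # f1's mother (DQ6/DQ6) and f2's father (no DQ6): both excluded
        assert tab.n_uninformative_parents == 3  # plus f0's mother (no DQ6)

    def test_null_transmission_rate_half(self):
        cfg = syndata.default_cohort_config(50, 50, seed=31)
        cfg.effect_lnors = {k: 0.0 for k in cfg.effect_lnors}
        cfg.ld_links = []
        trios = syndata.generate_trios(cfg, 300)
        tab = transmission_counts(trios, "DQB1*03:01")
        frac = tab.t_high + tab.t_low
        total = tab.n_informative_parents
        assert abs(frac / total - 0.5) < 0.1


class TestStrataDifference:
    def test_identical_ratios_zero(self):
        tab = TransmissionTable(DQ6, 1.75, t_high=4, nt_high=8, t_low=2, nt_low=4)
        assert strata_difference_stat(tab, continuity=False) == pytest.approx(0.0)

    def test_log_ratio_arithmetic(self):
        tab = TransmissionTable(DQ6, 1.75, t_high=1, nt_high=4, t_low=1, nt_low=8)
        got = strata_difference_stat(tab, continuity=False)
        assert got == pytest.approx(math.log(2))

    def test_zero_cell_policy(self):
        tab = TransmissionTable(DQ6, 1.75, t_high=0, nt_high=4, t_low=1, nt_low=8)
        with pytest.raises(family_tdt.ZeroCellError):
            strata_difference_stat(tab, continuity=False)
        assert math.isfinite(strata_difference_stat(tab, continuity=True))

    def test_raw_ratio_form(self):
        tab = TransmissionTable(DQ6, 1.75, t_high=4, nt_high=2, t_low=1, nt_low=2)
        got = strata_difference_stat(tab, continuity=False, form="ratio")
        assert got == pytest.approx(2.0 - 0.5)


class TestTdtPermutation:
    def test_single_genotype_reduces_to_d(self, hand_trios):
        res = tdt_permutation_test(hand_trios, [DQ6], n_perm=50, seed=1)
        th, nth, tl, ntl = 1.5, 1.5, 1.5, 2.5
        expected = math.log(th / nth) - math.log(tl / ntl)
        assert res.observed_stat == pytest.approx(expected)

    def test_add_one_rule(self, hand_trios):
        res = tdt_permutation_test(hand_trios, [DQ6], n_perm=99, seed=2)
        assert res.p_value == (res.n_as_extreme + 1) / 100

    def test_null_trios_calibrated(self):
        """Over replicate null trio sets the permutation p is roughly
        uniform (checked loosely through its mean and range)."""
        ps = []
        for rep in range(12):
            cfg = syndata.default_cohort_config(
                50, 50, interaction_beta=0.0, seed=800 + rep
            )
            cfg.ld_links = []
            trios = syndata.generate_trios(cfg, 120)
            ps.append(
                tdt_permutation_test(
                    trios, [DQ6, "DQB1*03:01"], n_perm=200, seed=rep
                ).p_value
            )
        assert 0.2 < np.mean(ps) < 0.8

    def test_interaction_shrinks_p(self):
        cfg = syndata.default_cohort_config(50, 50, interaction_beta=1.2, seed=41)
        cfg.ld_links = []
        trios = syndata.generate_trios(cfg, 400)
        res = tdt_permutation_test(
            trios, [DQ6, "DQB1*03:01"], n_perm=400, seed=3
        )
        assert res.observed_stat > 0
        assert res.p_value < 0.1

    def test_both_strata_required(self, hand_trios):
        for t in hand_trios:
            t.child.score = 3.0
        with pytest.raises(ValueError):
            tdt_permutation_test(hand_trios, [DQ6], n_perm=10, seed=0)
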