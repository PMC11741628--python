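"""Synthetic cohort and trio generator: contracts, determinism, and the
statistical structure downstream analyses rely on."""

import numpy as np
import pytest
from scipy import stats

from kirmod import kir_core, syndata
from kirmod.association import crude_ln_or, two_by_two
from kirmod.genotypes import carriage
from kirmod.syndata import (
    ConfigError,
    CohortParseError,
    default_cohort_config,
    generate_cohort,
    generate_cohort_frame,
    generate_trios,
    read_cohort,
    read_trios,
    single_genotype_config,
    write_cohort,
    write_trios,
)


class TestGenerateCohort:
    def test_zero_cases_all_controls(self):
        cfg = default_cohort_config(0, 10, seed=1)
        recs = generate_cohort(cfg)
        assert len(recs) == 10
        assert all(r.case_status == "control" for r in recs)

    def test_exact_record_count(self):
        cfg = default_cohort_config(37, 61, seed=2)
        recs = generate_cohort(cfg)
        assert sum(r.case_status == "case" for r in recs) == 37
        assert sum(r.case_status == "control" for r in recs) == 61

    def test_deterministic_for_fixed_seed(self):
        cfg = default_cohort_config(50, 50, seed=9)
        a = generate_cohort_frame(cfg)
        b = generate_cohort_frame(default_cohort_config(50, 50, seed=9))
        assert a.equals(b)

    def test_inconsistent_labels_rejected(self):
        cfg = default_cohort_config(10, 10)
        cfg.effect_lnors["DQB1*09:99"] = -1.0
        with pytest.raises(ConfigError):
            generate_cohort(cfg)

    def test_bad_probability_rejected(self):
        cfg = default_cohort_config(10, 10)
        cfg.genotype_freqs["DQB1*03:01"] = 1.4
        with pytest.raises(ConfigError):
            generate_cohort(cfg)

    def test_crude_lnor_tracks_generative_effect(self):
        """Monte-Carlo oracle: with one genotype of effect -2 and no
        interaction/LD, the crude ln[OR] lands within +-0.3 of -2."""
        cfg = single_genotype_config(
            5000, 5000, effect=-2.0, carriage_p=0.3, seed=42
        )
        df = generate_cohort_frame(cfg)
        a, b, c, d = two_by_two(df, carriage(df, "DQB1*03:01"))
        assert crude_ln_or(a, b, c, d) == pytest.approx(-2.0, abs=0.3)

    def test_kir_independent_of_hla_without_ld(self):
        cfg = default_cohort_config(2000, 2000, seed=5)
        cfg.ld_links = []
        df = generate_cohort_frame(cfg)
        kir = df["kir_genes"].str.contains("KIR2DL2").to_numpy()
        hla = np.asarray(carriage(df, "DQB1*03:01"), dtype=bool)
        table = np.array([
            [(kir & hla).sum(), (kir & ~hla).sum()],
            [(~kir & hla).sum(), (~kir & ~hla).sum()],
        ])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.001

    def test_ld_link_enriches_class1_allele(self):
        cfg = default_cohort_config(2000, 2000, seed=6)
        df = generate_cohort_frame(cfg)
        dr3 = np.asarray(
            carriage(df, "DRB1*03:01-DQA1*05:01-DQB1*02:01"), dtype=bool
        )
        b8 = np.asarray(carriage(df, "B*08:01"), dtype=bool)
        assert b8[dr3].mean() > b8[~dr3].mean()

    def test_score_matches_per_record_profile(self):
        """The generator's vectorised score agrees with the reference
        per-individual scoring pipeline."""
        recs = generate_cohort(default_cohort_config(40, 40, seed=13))
        for r in recs:
            prof = kir_core.profile_individual(
                r.kir_genes, r.hla_class1, unknown="ignore"
            )
            assert prof.score == pytest.approx(r.score)
            assert prof.stratum == r.stratum


class TestCohortIO:
    def test_roundtrip_identity(self, tmp_path):
        recs = generate_cohort(default_cohort_config(10, 10, seed=4))
        path = tmp_path / "cohort.tsv"
        write_cohort(recs, path)
        back = read_cohort(path)
        assert len(back) == len(recs)
        for x, y in zip(recs, back):
            assert (x.id, x.case_status, x.sex) == (y.id, y.case_status, y.sex)
            assert x.kir_genes == y.kir_genes
            assert x.hla_class1 == y.hla_class1
            assert x.hla_class2 == y.hla_class2
            assert (x.hap1, x.hap2) == (y.hap1, y.hap2)

    def test_empty_cohort_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_cohort([], path)
        assert path.read_text().count("\n") == 1
        assert read_cohort(path) == []

    def test_three_alleles_at_locus_is_parse_error(self, tmp_path):
        recs = generate_cohort(default_cohort_config(2, 2, seed=4))
        path = tmp_path / "bad.tsv"
        write_cohort(recs, path)
        lines = path.read_text().splitlines()
        parts = lines[2].split("\t")
        parts[4] = "A*01:01;A*02:01"  # third allele smuggled into A1
        lines[2] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(CohortParseError, match="line 3"):
            read_cohort(path)

    def test_wrong_field_count_names_line(self, tmp_path):
        path = tmp_path / "trunc.tsv"
        recs = generate_cohort(default_cohort_config(2, 2, seed=4))
        write_cohort(recs, path)
        with open(path, "a", encoding="utf-8") as fh:
            fh.write("too\tfew\tfields\n")
        with pytest.raises(CohortParseError, match="line 6"):
            read_cohort(path)


class TestTrios:
    def test_children_union_of_parental_haplotypes(self):
        cfg = default_cohort_config(100, 100, seed=8)
        trios = generate_trios(cfg, 3)
        assert len(trios) == 3
        for t in trios:
            assert t.child.hap1 in (t.father.hap1, t.father.hap2)
            assert t.child.hap2 in (t.mother.hap1, t.mother.hap2)
            assert t.child.case_status == "case"

    def test_deterministic(self):
        cfg = default_cohort_config(100, 100, seed=8)
        a = generate_trios(cfg, 5)
        b = generate_trios(default_cohort_config(100, 100, seed=8), 5)
        for x, y in zip(a, b):
            assert x.child.hap1 == y.child.hap1
            assert x.child.kir_genes == y.child.kir_genes

    def test_null_transmission_near_half(self):
        """Binomial oracle: with all effects zero, any haplotype is
        transmitted to the affected child about half the time."""
        cfg = default_cohort_config(100, 100, seed=21)
        cfg.effect_lnors = {k: 0.0 for k in cfg.effect_lnors}
        cfg.interaction_beta = 0.0
        cfg.ld_links = []
        trios = generate_trios(cfg, 400)
        from kirmod.family_tdt import _per_trio_counts

        t, nt, _ = _per_trio_counts(trios, "DQB1*03:01")
        total = t.sum() + nt.sum()
        frac = t.sum() / total
        # exact binomial bound at the 1e-3 level
        lo, hi = stats.binom.interval(0.999, int(total), 0.5)
        assert lo <= t.sum() <= hi, frac

    def test_protective_genotype_under_transmitted(self):
        cfg = default_cohort_config(100, 100, seed=22)
        trios = generate_trios(cfg, 300)
        from kirmod.family_tdt import _per_trio_counts

        t, nt, _ = _per_trio_counts(trios, "DQA1*01:02-DQB1*06:02")
        assert t.sum() < nt.sum()

    def test_n_families_validation(self):
        with pytest.raises(ConfigError):
            generate_trios(default_cohort_config(10, 10), 0)

    def test_trio_roundtrip(self, tmp_path):
        cfg = default_cohort_config(100, 100, seed=8)
        trios = generate_trios(cfg, 4)
        path = tmp_path / "trios.ped"
        write_trios(trios, path)
        back = read_trios(path)
        assert len(back) == 4
        for x, y in zip(trios, back):
            assert x.family_id == y.family_id
            assert x.child.hap1 == y.child.hap1
            # transmitted haplotypes (by content: indices are ambiguous for
            # homozygous parents) must be recovered
            fx = (x.father.hap1, x.father.hap2)[x.transmitted_father]
            fy = (y.father.hap1, y.father.hap2)[y.transmitted_father]
            mx = (x.mother.hap1, x.mother.hap2)[x.transmitted_mother]
            my = (y.mother.hap1, y.mother.hap2)[y.transmitted_mother]
            assert fx == fy and mx == my
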