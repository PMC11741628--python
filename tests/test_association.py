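"""Logistic association analysis: crude estimates, stratified and
interaction models, and their oracle equivalences."""

import math

import pytest

from kirmod import syndata
from kirmod.association import (
    GenotypeSkipped,
    SeparationError,
    ZeroCellError,
    crude_ln_or,
    crude_ln_or_ci,
    fit_logistic,
    genotype_effect,
    interaction_model,
    power_by_resampling,
    stepwise_score_vs_count,
    stratified_effect,
)
from conftest import frame_from_counts


class TestCrudeLnOr:
    # reference 2x2 tables with their published 2-d.p. estimates
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((26, 729, 2984, 1681), -3.91),
            ((361, 777, 2649, 1633), -1.25),
            ((252, 922, 2758, 1488), -1.91),
        ],
    )
    def test_reference_tables(self, cells, expected):
        assert round(crude_ln_or(*cells), 2) == expected

    def test_symmetric_table_is_zero(self):
        assert crude_ln_or(10, 10, 10, 10) == 0.0

    def test_zero_cell_raises_without_continuity(self):
        with pytest.raises(ZeroCellError):
            crude_ln_or(0, 10, 10, 10)

    def test_haldane_correction_explicit(self):
        got = crude_ln_or(0, 10, 10, 10, continuity=True)
        assert got == pytest.approx(math.log((0.5 * 10.5) / (10.5 * 10.5)))

    def test_ci_brackets_estimate(self):
        lnor, lo, hi = crude_ln_or_ci(26, 729, 2984, 1681)
        assert lo < lnor < hi


class TestFitLogistic:
    def test_single_predictor_equals_crude_lnor(self):
        """Closed-form 2x2 oracle: the ML coefficient of a lone binary
        predictor equals ln[(a d)/(b c)] to at least 6 significant digits."""
        df = frame_from_counts(26, 729, 2984, 1681)
        res = fit_logistic(df["status"], df[["g"]])["g"]
        expected = crude_ln_or(26, 729, 2984, 1681)
        assert res.ln_or == pytest.approx(expected, rel=1e-7)

    def test_uninformative_predictor_near_zero(self):
        df = frame_from_counts(50, 50, 50, 50)
        res = fit_logistic(df["status"], df[["g"]])["g"]
        assert abs(res.ln_or) < 1e-6

    def test_separation_is_diagnosed(self):
        df = frame_from_counts(50, 1, 1, 50)
        df["g2"] = df["status"]  # perfectly separating predictor
        with pytest.raises(SeparationError):
            fit_logistic(df["status"], df[["g2"]])

    def test_needs_both_outcomes(self):
        df = frame_from_counts(5, 0, 5, 0).assign(status=1)
        with pytest.raises(ValueError):
            fit_logistic(df["status"], df[["g"]])

    def test_wald_ci_contains_estimate(self):
        df = frame_from_counts(30, 60, 70, 40)
        res = fit_logistic(df["status"], df[["g"]])["g"]
        assert res.ci_low <= res.ln_or <= res.ci_high
        assert 0 <= res.p_value <= 1


class TestStratifiedEffect:
    def test_interaction_weakens_protection_in_high_stratum(self, interaction_cohort):
        _, df = interaction_cohort
        hi, lo = stratified_effect(df, "DQA1*01:02-DQB1*06:02")
        assert lo.ln_or < hi.ln_or  # stronger protection at low score

    def test_counts_partition_cohort(self, interaction_cohort):
        _, df = interaction_cohort
        hi, lo = stratified_effect(df, "DQB1*03:01")
        assert sum(hi.n_by_cell) + sum(lo.n_by_cell) == len(df)

    def test_min_case_carrier_filter(self, small_cohort):
        _, df = small_cohort
        with pytest.raises(GenotypeSkipped):
            stratified_effect(df, "DQB1*03:01", min_cases=10**6)


class TestInteractionModel:
    def test_recovers_generative_interaction(self):
        cfg = syndata.single_genotype_config(
            2000, 2000, interaction_beta=0.9, seed=77
        )
        df = syndata.generate_cohort_frame(cfg)
        res = interaction_model(df, "DQB1*03:01")
        assert res.p_value < 0.05
        assert 0.3 < res.ln_or < 1.5

    def test_null_interaction_not_significant_mostly(self, null_cohort):
        _, df = null_cohort
        res = interaction_model(df, "DQB1*03:01")
        assert abs(res.ln_or) < 0.5

    def test_aic_of_richer_model_bounded(self, null_cohort):
        """Adding k parameters can raise the AIC by at most 2k."""
        _, df = null_cohort
        inter = interaction_model(df, "DQB1*03:01")
        main = genotype_effect(df, "DQB1*03:01")
        assert inter.aic <= main.aic + 2 * 2 + 1e-9

    def test_continuous_vs_stratified_modes_differ(self, interaction_cohort):
        _, df = interaction_cohort
        cont = interaction_model(df, "DQB1*03:01", score_mode="continuous")
        strat = interaction_model(df, "DQB1*03:01", score_mode="stratified")
        assert cont.model_formula != "" and strat.aic != pytest.approx(cont.aic)


class TestPowerByResampling:
    def test_null_power_near_alpha_and_odd_size_rejected(self, null_cohort):
        _, df = null_cohort
        power = power_by_resampling(
            df, "DQB1*03:01", sample_sizes=[400], n_boot=60, seed=1
        )
        assert 0.0 <= power[400] <= 0.2
        with pytest.raises(ValueError):
            power_by_resampling(df, "DQB1*03:01", sample_sizes=[401], n_boot=5)

    def test_power_grows_with_sample_size(self, interaction_cohort):
        _, df = interaction_cohort
        power = power_by_resampling(
            df, "DQA1*01:02-DQB1*06:02", sample_sizes=[300, 2400],
            n_boot=60, score_mode="continuous", seed=2,
        )
        assert power[2400] >= power[300]


class TestStepwiseScoreVsCount:
    def test_causal_score_outcompetes_count(self):
        """When the weighted score is the generative interaction variable,
        backward selection from a model with both standardised interaction
        terms retains the score rather than the unit-weight count, across
        replicate cohorts."""
        from kirmod import kir_core

        unit = kir_core.ScoreWeights.default().unit()
        retained = []
        for seed in (400, 401, 402):
            cfg = syndata.default_cohort_config(
                1500, 1500, interaction_beta=0.9, seed=seed
            )
            recs = syndata.generate_cohort(cfg)
            counts = [
                kir_core.profile_individual(
                    r.kir_genes, r.hla_class1, weights=unit, unknown="ignore"
                ).score
                for r in recs
            ]
            df = syndata.cohort_to_frame(recs)
            df["count"] = counts
            retained.append(
                stepwise_score_vs_count(df, "DQA1*01:02-DQB1*06:02")
            )
        assert retained.count("score") >= 2
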