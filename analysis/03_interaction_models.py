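#!/usr/bin/env python
"""Dose-effect modelling: genotype-by-score interaction as a continuous vs
stratified term, AIC comparison, and score-vs-count stepwise selection.

Expects results/cohort.tsv (scored on the fly).
"""

import pathlib

import pandas as pd

from kirmod import association, kir_core, syndata

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
DQ6 = "DQA1*01:02-DQB1*06:02"
GENOTYPES = [DQ6, "DQB1*03:01"]


def load_scored() -> pd.DataFrame:
    records = syndata.read_cohort(OUT / "cohort.tsv")
    weights = kir_core.ScoreWeights.default()
    unit = weights.unit()
    rows = []
    for r in records:
        prof = kir_core.profile_individual(
            r.kir_genes, r.hla_class1, weights=weights, unknown="ignore"
        )
        cnt = kir_core.profile_individual(
            r.kir_genes, r.hla_class1, weights=unit, unknown="ignore"
        )
        r.score, r.stratum = prof.score, prof.stratum
        rows.append(cnt.score)
    df = syndata.cohort_to_frame(records)
    df["count"] = rows
    return df


def main() -> None:
    df = load_scored()
    rows = []
    for g in GENOTYPES:
        for mode in ("continuous", "stratified"):
            res = association.interaction_model(df, g, score_mode=mode)
            rows.append({"genotype": g, "score_mode": mode,
                         "interaction": round(res.ln_or, 3),
                         "p": res.p_value, "aic": round(res.aic, 1)})
    tab = pd.DataFrame(rows)
    tab.to_csv(OUT / "interaction_models.tsv", sep="\t", index=False)
    print(tab.to_string(index=False))

    kept = association.stepwise_score_vs_count(df, DQ6)
    print(f"backward step from a model with both standardised interaction "
          f"terms retains: {kept}")
    print("A positive interaction term means protection weakens as the "
          "score rises; the continuous-score model is the dose-effect "
          "formulation.")


if __name__ == "__main__":
    main()
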