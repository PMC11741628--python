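#!/usr/bin/env python
"""Score the cohort (functional iKIR pairs -> weighted score -> high/low
strata) and report the whole-cohort vs per-stratum protective effect of the
DQ6-like genotype at several thresholds.

Expects results/cohort.tsv from 01_simulate_cohorts.py.
"""

import pathlib

import pandas as pd

from kirmod import association, kir_core, syndata

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
DQ6 = "DQA1*01:02-DQB1*06:02"


def main() -> None:
    records = syndata.read_cohort(OUT / "cohort.tsv")
    weights = kir_core.ScoreWeights.default()
    for r in records:
        prof = kir_core.profile_individual(
            r.kir_genes, r.hla_class1, weights=weights, unknown="ignore"
        )
        r.score, r.stratum = prof.score, prof.stratum
    df = syndata.cohort_to_frame(records)

    print(f"weight table {weights.version}; score range "
          f"{df.score.min():.2f}-{df.score.max():.2f}; "
          f"low fraction at 1.75: {(df.score <= 1.75).mean():.2f}")

    rows = []
    whole = association.genotype_effect(df, DQ6)
    rows.append({"threshold": "-", "group": "whole", "ln_or": whole.ln_or,
                 "ci_low": whole.ci_low, "ci_high": whole.ci_high,
                 "p": whole.p_value})
    for thr in (1.5, 1.75, 2.0, 2.5):
        hi, lo = association.stratified_effect(df, DQ6, threshold=thr)
        for res in (hi, lo):
            rows.append({"threshold": thr, "group": f"iKIR {res.stratum}",
                         "ln_or": res.ln_or, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p_value})
    tab = pd.DataFrame(rows).round(3)
    tab.to_csv(OUT / "stratified_dq6.tsv", sep="\t", index=False)
    print(tab.to_string(index=False))
    print("Protection is consistently stronger (more negative ln[OR]) in the "
          "low-score stratum at every threshold when the generative "
          "interaction is positive.")


if __name__ == "__main__":
    main()
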