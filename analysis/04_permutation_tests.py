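#!/usr/bin/env python
"""Permutation tests for iKIR-score modification: single-genotype test for
the DQ6-like genotype and the frequency-weighted multi-genotype statistic
over all protective genotypes, with the empirical null built by permuting
scores across individuals.
"""

import json
import pathlib

from kirmod import kir_core, permutation, syndata

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
DQ6 = "DQA1*01:02-DQB1*06:02"
PROTECTIVE = [DQ6, "DQB1*03:01"]


def main() -> None:
    records = syndata.read_cohort(OUT / "cohort.tsv")
    for r in records:
        prof = kir_core.profile_individual(
            r.kir_genes, r.hla_class1, unknown="ignore"
        )
        r.score, r.stratum = prof.score, prof.stratum
    df = syndata.cohort_to_frame(records)

    results = {}
    single = permutation.permutation_test(df, DQ6, n_perm=100_000, seed=1)
    results["single_genotype"] = single
    multi = permutation.permutation_test(df, PROTECTIVE, n_perm=100_000, seed=2)
    results["weighted_multi_genotype"] = multi

    payload = {}
    for name, res in results.items():
        payload[name] = {
            "observed_stat": res.observed_stat,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
            "weights": res.weights,
        }
        print(f"{name}: S = {res.observed_stat:.3f}, "
              f"p = {res.p_value:.2e} ({res.n_perm} permutations)")
    (OUT / "permutation_tests.json").write_text(json.dumps(payload, indent=2))
    print("S > 0 with a small p: the protective ln[OR]s are systematically "
          "less negative in the high-score stratum, beyond what score "
          "shuffling can produce.")


if __name__ == "__main__":
    main()
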