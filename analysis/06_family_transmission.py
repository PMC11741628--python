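#!/usr/bin/env python
"""Stratified transmission analysis on the synthetic trios: per-stratum
transmission tables for the protective genotypes and the permutation p for
the cross-strata log-ratio difference.
"""

import pathlib

import pandas as pd

from kirmod import family_tdt, kir_core, syndata

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
GENOTYPES = ["DQA1*01:02-DQB1*06:02", "DQB1*03:01"]


def main() -> None:
    trios = syndata.read_trios(OUT / "trios.ped")
    for t in trios:
        prof = kir_core.profile_individual(
            t.child.kir_genes, t.child.hla_class1, unknown="ignore"
        )
        t.child.score = prof.score

    rows = []
    for g in GENOTYPES:
        tab = family_tdt.transmission_counts(trios, g)
        d = family_tdt.strata_difference_stat(tab)
        rows.append({
            "genotype": g, "T_high": tab.t_high, "NT_high": tab.nt_high,
            "T_low": tab.t_low, "NT_low": tab.nt_low,
            "log_ratio_difference": round(d, 3),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "transmission_tables.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    res = family_tdt.tdt_permutation_test(
        trios, GENOTYPES, n_perm=100_000, seed=3
    )
    print(f"aggregate D = {res.observed_stat:.3f}, "
          f"permutation p = {res.p_value:.2e}")
    print("D > 0: protective haplotypes are less under-transmitted to "
          "affected children with many functional iKIR pairs.")


if __name__ == "__main__":
    main()
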