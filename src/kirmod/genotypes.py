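"""HLA genotype definitions and carriage predicates on cohort tables.

A "genotype" here is one class I allele, or one to three class II alleles at
DRB1/DQA1/DQB1.  Multi-allele class II genotypes may be required in *cis*
(all alleles on one parental haplotype), in *trans*, or satisfied either way
(the default, since both cis- and trans-acting associations are documented).
Carriage is dominant-coded: an individual either carries the genotype or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS1_LOCI = ("A", "B", "C")
CLASS2_LOCI = ("DRB1", "DQA1", "DQB1")
_LOCUS_ORDER = {loc: i for i, loc in enumerate(CLASS2_LOCI)}

CLASS1_COLUMNS = {"A": ("A1", "A2"), "B": ("B1", "B2"), "C": ("C1", "C2")}
CLASS2_COLUMNS = {
    "DRB1": ("DRB1_1", "DRB1_2"),
    "DQA1": ("DQA1_1", "DQA1_2"),
    "DQB1": ("DQB1_1", "DQB1_2"),
}


class GenotypeError(ValueError):
    """Malformed genotype definition."""


def locus_of(allele: str) -> str:
    if "*" not in allele:
        raise GenotypeError(f"allele {allele!r} has no locus prefix")
    return allele.split("*", 1)[0]


@dataclass(frozen=True)
class GenotypeDef:
    """A canonical, order-invariant genotype definition."""

    alleles: tuple[str, ...]
    phase_mode: str = "either"  # cis | trans | either

    def __post_init__(self):
        if not 1 <= len(self.alleles) <= 3:
            raise GenotypeError("genotype must have 1-3 alleles")
        if self.phase_mode not in ("cis", "trans", "either"):
            raise GenotypeError(f"bad phase_mode {self.phase_mode!r}")
        loci = [locus_of(a) for a in self.alleles]
        class1 = [l for l in loci if l in CLASS1_LOCI]
        class2 = [l for l in loci if l in CLASS2_LOCI]
        if class1 and class2:
            raise GenotypeError("genotype mixes class I and class II loci")
        if class1 and len(self.alleles) > 1:
            raise GenotypeError("class I genotypes are single alleles")
        if not class1 and not class2:
            raise GenotypeError(f"unrecognised loci in {self.alleles}")
        for l in set(loci):
            if loci.count(l) > 2:
                raise GenotypeError(f"more than 2 alleles at locus {l}")
        # canonical order: locus order, then allele name
        ordered = tuple(
            sorted(self.alleles, key=lambda a: (_LOCUS_ORDER.get(locus_of(a), -1), a))
        )
        object.__setattr__(self, "alleles", ordered)

    @property
    def label(self) -> str:
        return "-".join(self.alleles)

    @property
    def is_class1(self) -> bool:
        return locus_of(self.alleles[0]) in CLASS1_LOCI

    @classmethod
    def parse(cls, label: str, phase_mode: str = "either") -> "GenotypeDef":
        return cls(alleles=tuple(label.split("-")), phase_mode=phase_mode)


def _allele_present(df: pd.DataFrame, allele: str) -> np.ndarray:
    locus = locus_of(allele)
    cols = CLASS1_COLUMNS.get(locus) or CLASS2_COLUMNS.get(locus)
    if cols is None:
        raise GenotypeError(f"unknown locus for allele {allele!r}")
    out = np.zeros(len(df), dtype=bool)
    for c in cols:
        out |= (df[c] == allele).to_numpy()
    return out


def _cis_satisfied(df: pd.DataFrame, alleles: tuple[str, ...]) -> np.ndarray:
    """All alleles on a single class II haplotype (hap1 or hap2 string)."""
    def hap_has_all(hap: str) -> bool:
        parts = set(hap.split("|")) if isinstance(hap, str) and hap else set()
        return all(a in parts for a in alleles)

    h1 = df["hap1"].map(hap_has_all).to_numpy(dtype=bool)
    h2 = df["hap2"].map(hap_has_all).to_numpy(dtype=bool)
    return h1 | h2


def carriage(df: pd.DataFrame, genotype: GenotypeDef | str) -> np.ndarray:
    """Boolean carriage vector for a genotype over a cohort table.

    ``either``: every allele present somewhere in the individual's genotype.
    ``cis``: every allele on one phased haplotype (requires hap1/hap2).
    ``trans``: all alleles present but *not* jointly on a single haplotype.
    """
    if isinstance(genotype, str):
        genotype = GenotypeDef.parse(genotype)
    present = np.ones(len(df), dtype=bool)
    for a in genotype.alleles:
        present &= _allele_present(df, a)
    if genotype.is_class1 or len(genotype.alleles) == 1:
        return present
    if genotype.phase_mode == "either":
        return present
    cis = _cis_satisfied(df, genotype.alleles)
    if genotype.phase_mode == "cis":
        return present & cis
    return present & ~cis


def carriage_frequency(df: pd.DataFrame, genotype: GenotypeDef | str) -> float:
    """Fraction of the analysed cohort carrying the genotype."""
    return float(carriage(df, genotype).mean())
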