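"""KIR ligand assignment, functional iKIR pairs, the iKIR score and stratification.

Inhibitory killer-cell immunoglobulin-like receptors (iKIRs) bind HLA class I
molecules in broad allele groups: KIR2DL1 binds C2-group HLA-C, KIR2DL2 and
KIR2DL3 bind C1-group HLA-C, KIR3DL1 binds Bw4-motif HLA-B (and some HLA-A)
alleles, and KIR3DL2 binds HLA-A*03/A*11.  Because the KIR and HLA loci sit on
different chromosomes they segregate independently, so an individual may carry
an iKIR gene without the gene for its ligand.  An iKIR present together with
its ligand is called *functional*; the iKIR score sums interaction-strength
weights over an individual's functional pairs, and a threshold on the score
splits a cohort into "high" and "low" strata.
"""

from __future__ import annotations

import functools
import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import yaml

log = logging.getLogger(__name__)

IKIR_GENES = ("KIR2DL1", "KIR2DL2", "KIR2DL3", "KIR3DL1", "KIR3DL2")

#: ligand-group labels used throughout the package
C1, C2, BW4_80I, BW4_80T, A3A11 = "C1", "C2", "Bw4-80I", "Bw4-80T", "A3A11"


class LigandTableError(KeyError):
    """An HLA allele could not be resolved in the allele->ligand table."""


class WeightError(KeyError):
    """A functional pair has no weight in the configured weight table."""


def _load_packaged_yaml(name: str) -> dict:
    ref = importlib.resources.files("kirmod.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class LigandTable:
    """Allele->ligand-group lookup with most-specific-prefix matching."""

    version: str
    c1: tuple[str, ...]
    c2: tuple[str, ...]
    bw4_80i: tuple[str, ...]
    bw4_80t: tuple[str, ...]
    a3a11: tuple[str, ...]

    @classmethod
    @functools.cache
    def default(cls) -> "LigandTable":
        raw = _load_packaged_yaml("ligand_groups.yaml")
        return cls(
            version=raw["version"],
            c1=tuple(raw["c1"]),
            c2=tuple(raw["c2"]),
            bw4_80i=tuple(raw["bw4_80i"]),
            bw4_80t=tuple(raw["bw4_80t"]),
            a3a11=tuple(raw["a3a11"]),
        )

    def _match(self, allele: str, prefixes: Iterable[str]) -> bool:
        return _best_prefix_len(allele, prefixes) > 0

    def groups_of(self, allele: str) -> set[str]:
        """All ligand groups an allele belongs to (most specific prefix wins
        within the Bw4 80I/80T split)."""
        out: set[str] = set()
        if self._match(allele, self.c1):
            out.add(C1)
        if self._match(allele, self.c2):
            out.add(C2)
        # 80I vs 80T may both have prefixes matching (e.g. B*27 group split
        # at two-field level); keep the most specific match only.
        i_len = _best_prefix_len(allele, self.bw4_80i)
        t_len = _best_prefix_len(allele, self.bw4_80t)
        if i_len or t_len:
            out.add(BW4_80I if i_len >= t_len else BW4_80T)
        if self._match(allele, self.a3a11):
            out.add(A3A11)
        return out


def _best_prefix_len(allele: str, prefixes: Iterable[str]) -> int:
    best = 0
    for p in prefixes:
        if allele == p or allele.startswith(p + ":"):
            best = max(best, len(p))
    return best


@dataclass(frozen=True)
class LigandProfile:
    """Which KIR-ligand groups an individual's class I alleles encode.

    ``bw4`` is ``"absent"``, ``"Bw4-80I"`` or ``"Bw4-80T"`` (80I dominates if
    both subtypes are present, being the stronger interaction); ``c1`` and
    ``c2`` may both be true for C-group heterozygotes.
    """

    bw4: str = "absent"
    c1: bool = False
    c2: bool = False
    a3a11: bool = False


def assign_ligands(
    hla_class1: Sequence[str],
    table: LigandTable | None = None,
    unknown: Literal["error", "ignore"] = "error",
) -> LigandProfile:
    """Derive the ligand profile from a list of HLA-A/B/C allele names.

    ``unknown`` sets the policy for alleles absent from the table: ``"error"``
    raises :class:`LigandTableError`; ``"ignore"`` treats the allele as
    encoding no ligand (logged).
    """
    table = table or LigandTable.default()
    c1 = c2 = a3a11 = False
    has_80i = has_80t = False
    for allele in hla_class1:
        if not allele:
            continue
        groups = table.groups_of(allele)
        if not groups:
            locus = allele.split("*")[0]
            # HLA-A/B alleles without a Bw4/A3-A11 entry legitimately encode
            # no KIR ligand; an HLA-C allele must be C1 or C2.
            if locus == "C":
                if unknown == "error":
                    raise LigandTableError(
                        f"HLA-C allele {allele!r} not in ligand table "
                        f"{table.version}"
                    )
                log.warning("treating unknown HLA-C allele %s as no ligand", allele)
            continue
        c1 |= C1 in groups
        c2 |= C2 in groups
        a3a11 |= A3A11 in groups
        has_80i |= BW4_80I in groups
        has_80t |= BW4_80T in groups
    bw4 = BW4_80I if has_80i else (BW4_80T if has_80t else "absent")
    return LigandProfile(bw4=bw4, c1=c1, c2=c2, a3a11=a3a11)


@dataclass(frozen=True)
class ScoreWeights:
    """Versioned per-pair interaction weights for the iKIR score."""

    weights: Mapping[str, float]  # keyed "GENE/LIGAND", e.g. "KIR2DL1/C2"
    threshold_default: float = 1.75
    include_kir3dl2: bool = False
    version: str = "custom"

    def __post_init__(self):
        if not self.weights or not any(w > 0 for w in self.weights.values()):
            raise WeightError("weight table needs at least one positive weight")
        for k, w in self.weights.items():
            if not (w >= 0):
                raise WeightError(f"weight for {k} must be finite and >= 0")

    @classmethod
    @functools.cache
    def default(cls) -> "ScoreWeights":
        raw = _load_packaged_yaml("score_weights.yaml")
        return cls(
            weights=dict(raw["weights"]),
            threshold_default=float(raw["threshold_default"]),
            include_kir3dl2=bool(raw["include_kir3dl2"]),
            version=raw["version"],
        )

    def unit(self) -> "ScoreWeights":
        """Same pair structure with all weights 1 (iKIR *count*)."""
        return ScoreWeights(
            weights={k: 1.0 for k in self.weights},
            threshold_default=self.threshold_default,
            include_kir3dl2=self.include_kir3dl2,
            version=self.version + "+unit",
        )

    def weight_of(self, gene: str, ligand: str) -> float:
        key = f"{gene}/{ligand}"
        if key not in self.weights:
            raise WeightError(f"no weight for functional pair {key}")
        return self.weights[key]

    def attainable_range(self) -> tuple[float, float]:
        """(min, max) score attainable under this table.

        The maximum sums, per iKIR gene, the largest weight among that gene's
        ligand groups (a gene can form at most one scored pair per group and
        the Bw4 subtypes are mutually exclusive in a profile).
        """
        per_gene: dict[str, float] = {}
        for key, w in self.weights.items():
            gene = key.split("/")[0]
            if gene == "KIR3DL2" and not self.include_kir3dl2:
                continue
            per_gene[gene] = max(per_gene.get(gene, 0.0), w)
        return 0.0, sum(per_gene.values())


def functional_pairs(
    kir_genes: Iterable[str],
    ligands: LigandProfile,
    include_kir3dl2: bool = False,
) -> set[tuple[str, str]]:
    """Functional iKIR-ligand pairs: gene present *and* matching ligand present.

    KIR2DL1 pairs with C2, KIR2DL2 and KIR2DL3 each pair with C1, KIR3DL1
    pairs with the Bw4 subtype present, and (optionally) KIR3DL2 with A3/A11.
    """
    genes = set(kir_genes)
    pairs: set[tuple[str, str]] = set()
    if "KIR2DL1" in genes and ligands.c2:
        pairs.add(("KIR2DL1", C2))
    if "KIR2DL2" in genes and ligands.c1:
        pairs.add(("KIR2DL2", C1))
    if "KIR2DL3" in genes and ligands.c1:
        pairs.add(("KIR2DL3", C1))
    if "KIR3DL1" in genes and ligands.bw4 != "absent":
        pairs.add(("KIR3DL1", ligands.bw4))
    if include_kir3dl2 and "KIR3DL2" in genes and ligands.a3a11:
        pairs.add(("KIR3DL2", A3A11))
    return pairs


def ikir_score(
    pairs: Iterable[tuple[str, str]], weights: ScoreWeights | None = None
) -> float:
    """Sum of per-pair weights; with unit weights this is the iKIR count."""
    weights = weights or ScoreWeights.default()
    return float(sum(weights.weight_of(g, l) for g, l in pairs))


def stratify(score: float, threshold: float = 1.75) -> str:
    """``"low"`` iff score <= threshold, else ``"high"`` (ties go low)."""
    return "low" if score <= threshold else "high"


@dataclass(frozen=True)
class IKIRProfile:
    """An individual's functional pairs, score, and stratum at a threshold."""

    functional_pairs: frozenset[tuple[str, str]]
    score: float
    stratum: str
    weight_version: str = field(default="w-2024.1")


def profile_individual(
    kir_genes: Iterable[str],
    hla_class1: Sequence[str],
    weights: ScoreWeights | None = None,
    ligand_table: LigandTable | None = None,
    threshold: float | None = None,
    unknown: Literal["error", "ignore"] = "error",
) -> IKIRProfile:
    """Full pipeline: ligand profile -> functional pairs -> score -> stratum."""
    weights = weights or ScoreWeights.default()
    ligands = assign_ligands(hla_class1, ligand_table, unknown=unknown)
    pairs = functional_pairs(
        kir_genes, ligands, include_kir3dl2=weights.include_kir3dl2
    )
    score = ikir_score(pairs, weights)
    thr = weights.threshold_default if threshold is None else threshold
    return IKIRProfile(
        functional_pairs=frozenset(pairs),
        score=score,
        stratum=stratify(score, thr),
        weight_version=weights.version,
    )
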