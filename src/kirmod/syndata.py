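"""Synthetic case-control cohorts and family trios with the structure the
analysis assumes.

The generator emulates a European T1D case-control study: class II
DRB1-DQA1-DQB1 haplotypes with protective and detrimental effects on a
logistic disease model, KIR genes inherited independently of HLA (different
chromosomes), optional class I / class II linkage injected as conditional
odds multipliers, and an iKIR-score-by-protective-genotype interaction of
configurable size.  Phase is explicit: every individual carries two class II
haplotypes, so cis/trans genotype predicates are exercised downstream.

The disease model is
``logit P(case) = b0 + sum_g beta_g * carr_g
+ beta_int * score * carr_protective + beta_sex * male``;
the intercept ``b0`` is solved numerically so the population case fraction
matches ``n_cases/(n_cases+n_controls)`` and records are then filled by
rejection sampling, mirroring case-control (not prospective) ascertainment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import kir_core
from .kir_core import LigandTable, ScoreWeights

KIR_GENES = kir_core.IKIR_GENES


class ConfigError(ValueError):
    """Inconsistent cohort configuration."""


class CohortParseError(ValueError):
    """Malformed cohort/trio file; message names the offending line."""


# --- default genetic architecture -------------------------------------------

#: class II haplotype completions for the common European genotype labels
HAPLOTYPE_COMPLETIONS: dict[str, tuple[str, str, str]] = {
    "DQA1*01:02-DQB1*06:02": ("DRB1*15:01", "DQA1*01:02", "DQB1*06:02"),
    "DQB1*03:01": ("DRB1*11:01", "DQA1*05:05", "DQB1*03:01"),
    "DRB1*03:01-DQA1*05:01-DQB1*02:01": ("DRB1*03:01", "DQA1*05:01", "DQB1*02:01"),
    "DQB1*03:02": ("DRB1*04:01", "DQA1*03:01", "DQB1*03:02"),
    "DQA1*02:01": ("DRB1*07:01", "DQA1*02:01", "DQB1*02:02"),
    "DQA1*01:03": ("DRB1*13:01", "DQA1*01:03", "DQB1*06:03"),
}

#: neutral filler haplotypes absorbing the residual frequency mass
FILLER_HAPLOTYPES: tuple[tuple[str, str, str], ...] = (
    ("DRB1*01:01", "DQA1*01:01", "DQB1*05:01"),
    ("DRB1*13:02", "DQA1*01:02", "DQB1*06:04"),
    ("DRB1*08:01", "DQA1*04:01", "DQB1*04:02"),
)

#: per-locus class I allele frequencies (normalised at load)
CLASS1_FREQS: dict[str, dict[str, float]] = {
    "A": {
        "A*01:01": 0.16, "A*02:01": 0.27, "A*03:01": 0.13, "A*11:01": 0.06,
        "A*24:02": 0.09, "A*23:01": 0.02, "A*25:01": 0.02, "A*26:01": 0.03,
        "A*32:01": 0.03, "A*68:01": 0.04, "A*29:02": 0.03, "A*31:01": 0.03,
        "A*30:01": 0.09,
    },
    "B": {
        "B*07:02": 0.13, "B*08:01": 0.12, "B*44:02": 0.08, "B*44:03": 0.05,
        "B*57:01": 0.04, "B*27:05": 0.04, "B*15:01": 0.06, "B*18:01": 0.05,
        "B*35:01": 0.06, "B*51:01": 0.05, "B*40:01": 0.06, "B*13:02": 0.03,
        "B*14:02": 0.04, "B*38:01": 0.03, "B*55:01": 0.03, "B*39:06": 0.13,
    },
    "C": {
        "C*07:01": 0.15, "C*07:02": 0.14, "C*04:01": 0.12, "C*03:04": 0.08,
        "C*05:01": 0.08, "C*06:02": 0.09, "C*02:02": 0.05, "C*01:02": 0.04,
        "C*08:02": 0.05, "C*16:01": 0.04, "C*12:03": 0.06, "C*15:02": 0.04,
        "C*03:03": 0.06,
    },
}

#: KIR gene carriage frequencies typical of European cohorts
DEFAULT_KIR_FREQS: dict[str, float] = {
    "KIR2DL1": 0.97,
    "KIR2DL2": 0.55,
    "KIR2DL3": 0.88,
    "KIR3DL1": 0.94,
    "KIR3DL2": 0.99,
}


@dataclass
class CohortConfig:
    """Generative configuration for a synthetic case-control cohort."""

    n_cases: int
    n_controls: int
    genotype_freqs: dict[str, float] = field(default_factory=dict)
    effect_lnors: dict[str, float] = field(default_factory=dict)
    interaction_beta: float = 0.0
    ld_links: list[tuple[str, str, float]] = field(default_factory=list)
    kir_gene_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_KIR_FREQS))
    class1_freqs: dict[str, dict[str, float]] = field(default_factory=lambda: {k: dict(v) for k, v in CLASS1_FREQS.items()})
    sex_ratio: float = 0.5  # probability female
    sex_effect_lnor: float = 0.2  # ln-odds for males (T1D male excess)
    interaction_targets: tuple[str, ...] | None = None  # default: protective labels
    seed: int = 0
    weights: ScoreWeights | None = None
    ligand_table: LigandTable | None = None
    threshold: float = 1.75

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("n_cases and n_controls must be >= 0")
        for label, p in self.genotype_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"carriage probability for {label} not in [0,1]")
        for g, p in self.kir_gene_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"KIR frequency for {g} not in [0,1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio not in [0,1]")
        unknown = set(self.effect_lnors) - set(self.genotype_freqs)
        if unknown:
            raise ConfigError(
                f"effect_lnors labels missing from genotype_freqs: {sorted(unknown)}"
            )
        if self.interaction_targets is not None:
            missing = set(self.interaction_targets) - set(self.genotype_freqs)
            if missing:
                raise ConfigError(
                    f"interaction_targets missing from genotype_freqs: {sorted(missing)}"
                )
        for allele, label, mult in self.ld_links:
            if label not in self.genotype_freqs:
                raise ConfigError(f"ld_link references unknown genotype {label!r}")
            if not mult > 0:
                raise ConfigError("ld_link odds multiplier must be > 0")

    def protective_labels(self) -> tuple[str, ...]:
        if self.interaction_targets is not None:
            return tuple(self.interaction_targets)
        return tuple(g for g, b in self.effect_lnors.items() if b < 0)


def default_cohort_config(
    n_cases: int = 1000,
    n_controls: int = 1000,
    interaction_beta: float = 0.0,
    seed: int = 0,
) -> CohortConfig:
    """Study conditions for the synthetic analogue of a European T1D cohort.

    Carriage frequencies approximate control-group carriage of the major
    class II genotypes; effect sizes are dominant ln-odds on the same scale
    as published whole-cohort estimates.  One linkage link ties B*08:01 to
    the DR3 haplotype (the ancestral A1-B8-DR3 block).
    """
    return CohortConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        genotype_freqs={
            "DQA1*01:02-DQB1*06:02": 0.30,
            "DQB1*03:01": 0.30,
            "DRB1*03:01-DQA1*05:01-DQB1*02:01": 0.25,
            "DQB1*03:02": 0.25,
        },
        effect_lnors={
            "DQA1*01:02-DQB1*06:02": -2.5,
            "DQB1*03:01": -1.25,
            "DRB1*03:01-DQA1*05:01-DQB1*02:01": 1.4,
            "DQB1*03:02": 1.6,
        },
        interaction_beta=interaction_beta,
        ld_links=[("B*08:01", "DRB1*03:01-DQA1*05:01-DQB1*02:01", 3.0)],
        seed=seed,
    )


@dataclass
class IndividualRecord:
    id: str
    case_status: str  # "case" | "control"
    sex: str  # "F" | "M"
    kir_genes: frozenset[str]
    hla_class1: tuple[str, ...]  # A1,A2,B1,B2,C1,C2
    hla_class2: tuple[str, ...]  # DRB1_1,DRB1_2,DQA1_1,DQA1_2,DQB1_1,DQB1_2
    hap1: str = ""
    hap2: str = ""
    score: float = float("nan")
    stratum: str = ""


@dataclass
class TrioRecord:
    family_id: str
    child: IndividualRecord
    father: IndividualRecord
    mother: IndividualRecord
    transmitted_father: int = 0  # index (0/1) of the transmitted paternal haplotype
    transmitted_mother: int = 0


def single_genotype_config(
    n_cases: int = 2000,
    n_controls: int = 2000,
    effect: float = -1.25,
    carriage_p: float = 0.30,
    interaction_beta: float = 0.0,
    label: str = "DQB1*03:01",
    seed: int = 0,
) -> CohortConfig:
    """One labelled genotype on a neutral background: the configuration used
    for parameter-recovery and calibration studies, where the fitted
    interaction model coincides with the generative model."""
    return CohortConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        genotype_freqs={label: carriage_p},
        effect_lnors={label: effect},
        interaction_beta=interaction_beta,
        interaction_targets=(label,),
        seed=seed,
    )


# --- internal sampling machinery --------------------------------------------


def _resolve_haplotype(label: str) -> tuple[str, str, str]:
    if label in HAPLOTYPE_COMPLETIONS:
        return HAPLOTYPE_COMPLETIONS[label]
    alleles = label.split("-")
    by_locus: dict[str, str] = {}
    for a in alleles:
        by_locus[a.split("*", 1)[0]] = a
    return tuple(
        by_locus.get(loc, f"{loc}*99:01") for loc in ("DRB1", "DQA1", "DQB1")
    )  # type: ignore[return-value]


def _hap_string(h: tuple[str, str, str]) -> str:
    return "|".join(h)


@dataclass
class _Pool:
    """Resolved sampling machinery shared by cohort and trio generation."""

    hap_tuples: list[tuple[str, str, str]]
    hap_freqs: np.ndarray
    # per configured label: boolean satisfaction vector over pool haplotypes
    label_sat: dict[str, np.ndarray]
    class1_alleles: dict[str, list[str]]
    class1_freqs: dict[str, np.ndarray]
    kir_genes: list[str]
    kir_freqs: np.ndarray
    weights: ScoreWeights
    ligand_table: LigandTable
    # precomputed ligand flags per class I allele per locus
    flags: dict[str, dict[str, np.ndarray]]


def _hap_satisfies(hap: tuple[str, str, str], label: str) -> bool:
    parts = set(hap)
    return all(a in parts for a in label.split("-"))


def _build_pool(config: CohortConfig) -> _Pool:
    config.validate()
    labels = list(config.genotype_freqs)
    hap_tuples: list[tuple[str, str, str]] = []
    hap_freqs: list[float] = []
    for label, carriage_p in config.genotype_freqs.items():
        h = _resolve_haplotype(label)
        if h in hap_tuples:
            raise ConfigError(f"duplicate haplotype for genotype {label!r}")
        hap_tuples.append(h)
        hap_freqs.append(1.0 - math.sqrt(max(0.0, 1.0 - carriage_p)))
    used = sum(hap_freqs)
    if used > 1.0:
        raise ConfigError(f"haplotype frequencies sum to {used:.3f} > 1")
    residual = 1.0 - used
    fillers = [h for h in FILLER_HAPLOTYPES if h not in hap_tuples]
    for h in fillers:
        hap_tuples.append(h)
        hap_freqs.append(residual / len(fillers))
    freqs = np.asarray(hap_freqs, dtype=float)
    if freqs.sum() <= 0:
        raise ConfigError("haplotype frequencies sum to 0")
    freqs = freqs / freqs.sum()

    label_sat = {
        label: np.array([_hap_satisfies(h, label) for h in hap_tuples])
        for label in labels
    }

    weights = config.weights or ScoreWeights.default()
    table = config.ligand_table or LigandTable.default()
    c1_alleles, c1_freqs, flags = {}, {}, {}
    for locus, fd in config.class1_freqs.items():
        alleles = list(fd)
        f = np.asarray([fd[a] for a in alleles], dtype=float)
        c1_alleles[locus] = alleles
        c1_freqs[locus] = f / f.sum()
        groups = [table.groups_of(a) for a in alleles]
        flags[locus] = {
            g: np.array([g in gg for gg in groups])
            for g in (kir_core.C1, kir_core.C2, kir_core.BW4_80I,
                      kir_core.BW4_80T, kir_core.A3A11)
        }
    kir = list(config.kir_gene_freqs)
    return _Pool(
        hap_tuples=hap_tuples,
        hap_freqs=freqs,
        label_sat=label_sat,
        class1_alleles=c1_alleles,
        class1_freqs=c1_freqs,
        kir_genes=kir,
        kir_freqs=np.asarray([config.kir_gene_freqs[g] for g in kir]),
        weights=weights,
        ligand_table=table,
        flags=flags,
    )


def _score_from_flags(
    kir_carr: dict[str, np.ndarray],
    lig: dict[str, np.ndarray],
    weights: ScoreWeights,
) -> np.ndarray:
    """Vectorised iKIR score; agrees with kir_core.profile_individual."""
    w = weights.weights
    score = np.zeros(len(lig["c1"]))
    score += kir_carr["KIR2DL1"] * lig["c2"] * w.get("KIR2DL1/C2", 0.0)
    score += kir_carr["KIR2DL2"] * lig["c1"] * w.get("KIR2DL2/C1", 0.0)
    score += kir_carr["KIR2DL3"] * lig["c1"] * w.get("KIR2DL3/C1", 0.0)
    w3i = w.get("KIR3DL1/Bw4-80I", 0.0)
    w3t = w.get("KIR3DL1/Bw4-80T", 0.0)
    score += kir_carr["KIR3DL1"] * np.where(
        lig["bw4i"], w3i, np.where(lig["bw4t"], w3t, 0.0)
    )
    if weights.include_kir3dl2:
        score += kir_carr["KIR3DL2"] * lig["a3a11"] * w.get("KIR3DL2/A3A11", 0.0)
    return score


def _sample_batch(rng: np.random.Generator, pool: _Pool, config: CohortConfig, n: int):
    """Sample covariates for n individuals; returns a dict of arrays."""
    nh = len(pool.hap_tuples)
    h1 = rng.choice(nh, size=n, p=pool.hap_freqs)
    h2 = rng.choice(nh, size=n, p=pool.hap_freqs)
    carr = {
        label: sat[h1] | sat[h2] for label, sat in pool.label_sat.items()
    }
    # class I alleles: two independent draws per locus, with ld_links applied
    # as conditional odds multipliers on the allele's sampling weight for
    # individuals carrying the linked class II genotype
    class1_idx: dict[str, np.ndarray] = {}
    for locus, base in pool.class1_freqs.items():
        links = [
            (pool.class1_alleles[locus].index(a), label, mult)
            for a, label, mult in config.ld_links
            if a in pool.class1_alleles[locus]
        ]
        idx = np.empty((n, 2), dtype=int)
        if not links:
            idx[:, 0] = rng.choice(len(base), size=n, p=base)
            idx[:, 1] = rng.choice(len(base), size=n, p=base)
        else:
            # group rows by which links are active
            active = np.zeros(n, dtype=int)
            for bit, (_, label, _) in enumerate(links):
                active |= carr[label].astype(int) << bit
            for key in np.unique(active):
                rows = np.flatnonzero(active == key)
                w = base.copy()
                for bit, (ai, _, mult) in enumerate(links):
                    if key >> bit & 1:
                        w[ai] *= mult
                w = w / w.sum()
                idx[rows, 0] = rng.choice(len(base), size=len(rows), p=w)
                idx[rows, 1] = rng.choice(len(base), size=len(rows), p=w)
        class1_idx[locus] = idx

    kir_carr = {
        g: rng.random(n) < f for g, f in zip(pool.kir_genes, pool.kir_freqs)
    }
    lig = {"c1": np.zeros(n, bool), "c2": np.zeros(n, bool),
           "bw4i": np.zeros(n, bool), "bw4t": np.zeros(n, bool),
           "a3a11": np.zeros(n, bool)}
    keymap = {"c1": kir_core.C1, "c2": kir_core.C2, "bw4i": kir_core.BW4_80I,
              "bw4t": kir_core.BW4_80T, "a3a11": kir_core.A3A11}
    for locus, idx in class1_idx.items():
        for short, group in keymap.items():
            fl = pool.flags[locus][group]
            lig[short] |= fl[idx[:, 0]] | fl[idx[:, 1]]
    score = _score_from_flags(kir_carr, lig, pool.weights)
    female = rng.random(n) < config.sex_ratio

    lp = np.zeros(n)
    for label, beta in config.effect_lnors.items():
        lp += beta * carr[label]
    for label in config.protective_labels():
        lp += config.interaction_beta * score * carr[label]
    lp += config.sex_effect_lnor * (~female)
    return dict(
        h1=h1, h2=h2, carr=carr, class1_idx=class1_idx, kir_carr=kir_carr,
        lig=lig, score=score, female=female, lp=lp,
    )


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf

    def f(b0):
        return float(np.mean(expit(b0 + lp))) - target

    return brentq(f, -40.0, 40.0)


def _records_from_batch(batch, pool: _Pool, config: CohortConfig, status, rows, start_id):
    recs = []
    for k, i in enumerate(rows):
        a = batch["class1_idx"]["A"][i]
        b = batch["class1_idx"]["B"][i]
        c = batch["class1_idx"]["C"][i]
        class1 = (
            pool.class1_alleles["A"][a[0]], pool.class1_alleles["A"][a[1]],
            pool.class1_alleles["B"][b[0]], pool.class1_alleles["B"][b[1]],
            pool.class1_alleles["C"][c[0]], pool.class1_alleles["C"][c[1]],
        )
        hap1 = pool.hap_tuples[batch["h1"][i]]
        hap2 = pool.hap_tuples[batch["h2"][i]]
        class2 = (hap1[0], hap2[0], hap1[1], hap2[1], hap1[2], hap2[2])
        genes = frozenset(
            g for g in pool.kir_genes if batch["kir_carr"][g][i]
        )
        sc = float(batch["score"][i])
        recs.append(
            IndividualRecord(
                id=f"S{start_id + k:06d}",
                case_status="case" if status[i] else "control",
                sex="F" if batch["female"][i] else "M",
                kir_genes=genes,
                hla_class1=class1,
                hla_class2=class2,
                hap1=_hap_string(hap1),
                hap2=_hap_string(hap2),
                score=sc,
                stratum=kir_core.stratify(sc, config.threshold),
            )
        )
    return recs


def generate_cohort(config: CohortConfig) -> list[IndividualRecord]:
    """Generate exactly n_cases + n_controls individuals by rejection sampling.

    Reproducible for a fixed ``config.seed``.
    """
    pool = _build_pool(config)
    rng = np.random.default_rng(config.seed)
    total = config.n_cases + config.n_controls
    if total == 0:
        return []
    target = config.n_cases / total

    pilot = _sample_batch(rng, pool, config, max(2000, min(total, 20000)))
    b0 = _solve_intercept(pilot["lp"], target)

    cases: list[IndividualRecord] = []
    controls: list[IndividualRecord] = []
    guard = 0
    while len(cases) < config.n_cases or len(controls) < config.n_controls:
        guard += 1
        if guard > 1000:
            raise RuntimeError("rejection sampling failed to fill quotas")
        need_cases = config.n_cases - len(cases)
        need_controls = config.n_controls - len(controls)
        batch_n = int(1.6 * (need_cases + need_controls)) + 64
        batch = _sample_batch(rng, pool, config, batch_n)
        if np.isinf(b0):
            status = np.full(batch_n, b0 > 0)
        else:
            status = rng.random(batch_n) < expit(b0 + batch["lp"])
        case_rows = np.flatnonzero(status)[:need_cases]
        ctrl_rows = np.flatnonzero(~status)[:need_controls]
        cases.extend(
            _records_from_batch(batch, pool, config, status, case_rows, len(cases) + len(controls))
        )
        controls.extend(
            _records_from_batch(batch, pool, config, status, ctrl_rows,
                                len(cases) + len(controls))
        )
    recs = cases + controls
    for i, r in enumerate(recs):  # re-label ids uniquely and stably
        r.id = f"S{i:06d}"
    return recs


def cohort_to_frame(records: list[IndividualRecord]) -> pd.DataFrame:
    """Flatten records into the analysis table (one row per individual)."""
    rows = []
    for r in records:
        a1, a2, b1, b2, c1, c2 = r.hla_class1
        d1, d2, qa1, qa2, qb1, qb2 = r.hla_class2
        lig = kir_core.assign_ligands(r.hla_class1, unknown="ignore")
        rows.append({
            "id": r.id,
            "status": 1 if r.case_status == "case" else 0,
            "sex": r.sex,
            "kir_genes": ";".join(sorted(r.kir_genes)),
            "A1": a1, "A2": a2, "B1": b1, "B2": b2, "C1": c1, "C2": c2,
            "DRB1_1": d1, "DRB1_2": d2, "DQA1_1": qa1, "DQA1_2": qa2,
            "DQB1_1": qb1, "DQB1_2": qb2,
            "hap1": r.hap1, "hap2": r.hap2,
            "score": r.score, "stratum": r.stratum,
            "lig_bw4": int(lig.bw4 != "absent"),
            "lig_c1": int(lig.c1), "lig_c2": int(lig.c2),
        })
    cols = ["id", "status", "sex", "kir_genes", "A1", "A2", "B1", "B2",
            "C1", "C2", "DRB1_1", "DRB1_2", "DQA1_1", "DQA1_2", "DQB1_1",
            "DQB1_2", "hap1", "hap2", "score", "stratum",
            "lig_bw4", "lig_c1", "lig_c2"]
    return pd.DataFrame(rows, columns=cols)


def generate_cohort_frame(config: CohortConfig) -> pd.DataFrame:
    return cohort_to_frame(generate_cohort(config))


# --- trios -------------------------------------------------------------------


def generate_trios(config: CohortConfig, n_families: int) -> list[TrioRecord]:
    """Affected-child trios drawn from the same genetic architecture.

    Parents carry two full haplotypes each (class II haplotype plus linked
    class I alleles); the child inherits one haplotype from each parent and
    its own independently segregating KIR genes, and is resampled
    (transmission choices and KIR genes) until affected under the same
    logistic disease model.
    """
    if n_families < 1:
        raise ConfigError("n_families must be >= 1")
    pool = _build_pool(config)
    rng = np.random.default_rng(config.seed + 1)

    # class I haplotype sampling at the haplotype level, honouring ld_links
    def sample_parent_hap() -> dict:
        h = int(rng.choice(len(pool.hap_tuples), p=pool.hap_freqs))
        class1 = {}
        for locus, base in pool.class1_freqs.items():
            w = base.copy()
            for allele, label, mult in config.ld_links:
                if allele in pool.class1_alleles[locus] and _hap_satisfies(
                    pool.hap_tuples[h], label
                ):
                    w[pool.class1_alleles[locus].index(allele)] *= mult
            w = w / w.sum()
            class1[locus] = int(rng.choice(len(base), p=w))
        return {"h2": h, "c1": class1}

    def hap_class1_alleles(hap) -> tuple[str, str, str]:
        return tuple(
            pool.class1_alleles[loc][hap["c1"][loc]] for loc in ("A", "B", "C")
        )

    def make_individual(pid, sex, hapA, hapB, genes, status="control"):
        t1, t2 = pool.hap_tuples[hapA["h2"]], pool.hap_tuples[hapB["h2"]]
        a1, b1, c1 = hap_class1_alleles(hapA)
        a2, b2, c2 = hap_class1_alleles(hapB)
        class1 = (a1, a2, b1, b2, c1, c2)
        prof = kir_core.profile_individual(
            genes, class1, weights=pool.weights,
            ligand_table=pool.ligand_table, threshold=config.threshold,
            unknown="ignore",
        )
        return IndividualRecord(
            id=pid, case_status=status, sex=sex, kir_genes=frozenset(genes),
            hla_class1=class1,
            hla_class2=(t1[0], t2[0], t1[1], t2[1], t1[2], t2[2]),
            hap1=_hap_string(t1), hap2=_hap_string(t2),
            score=prof.score, stratum=prof.stratum,
        )

    def child_lp(child: IndividualRecord) -> float:
        hap_sets = (set(child.hap1.split("|")), set(child.hap2.split("|")))
        lp = 0.0
        for label, beta in config.effect_lnors.items():
            alleles = label.split("-")
            present = all(
                any(a in hs for hs in hap_sets) for a in alleles
            )
            if present:
                lp += beta
        for label in config.protective_labels():
            alleles = label.split("-")
            if all(any(a in hs for hs in hap_sets) for a in alleles):
                lp += config.interaction_beta * child.score
        lp += config.sex_effect_lnor * (child.sex == "M")
        return lp

    # intercept for a plausible sporadic-disease penetrance
    pilot = _sample_batch(rng, pool, config, 2000)
    b0 = _solve_intercept(pilot["lp"], 0.3)

    trios: list[TrioRecord] = []
    for fam in range(n_families):
        f_haps = (sample_parent_hap(), sample_parent_hap())
        m_haps = (sample_parent_hap(), sample_parent_hap())
        father = make_individual(f"F{fam:04d}_P1", "M", f_haps[0], f_haps[1],
                                 [g for g, p in config.kir_gene_freqs.items()
                                  if rng.random() < p])
        mother = make_individual(f"F{fam:04d}_P2", "F", m_haps[0], m_haps[1],
                                 [g for g, p in config.kir_gene_freqs.items()
                                  if rng.random() < p])
        child_sex = "F" if rng.random() < config.sex_ratio else "M"
        while True:
            tf = int(rng.integers(2))
            tm = int(rng.integers(2))
            genes = [g for g, p in config.kir_gene_freqs.items()
                     if rng.random() < p]
            child = make_individual(
                f"F{fam:04d}_C", child_sex, f_haps[tf], m_haps[tm], genes,
                status="case",
            )
            if rng.random() < expit(b0 + child_lp(child)):
                break
        trios.append(
            TrioRecord(
                family_id=f"F{fam:04d}", child=child, father=father,
                mother=mother, transmitted_father=tf, transmitted_mother=tm,
            )
        )
    return trios


# --- text I/O ----------------------------------------------------------------

_COHORT_COLUMNS = [
    "id", "status", "sex", "kir_genes", "A1", "A2", "B1", "B2", "C1", "C2",
    "DRB1_1", "DRB1_2", "DQA1_1", "DQA1_2", "DQB1_1", "DQB1_2", "hap1", "hap2",
]


def write_cohort(records: list[IndividualRecord], path) -> None:
    """UTF-8 tab-delimited cohort table (header always written)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_COHORT_COLUMNS) + "\n")
        for r in records:
            row = [
                r.id, str(1 if r.case_status == "case" else 0), r.sex,
                ";".join(sorted(r.kir_genes)), *r.hla_class1,
                r.hla_class2[0], r.hla_class2[1], r.hla_class2[2],
                r.hla_class2[3], r.hla_class2[4], r.hla_class2[5],
                r.hap1, r.hap2,
            ]
            fh.write("\t".join(row) + "\n")


def read_cohort(path) -> list[IndividualRecord]:
    """Parse a cohort table; malformed rows raise with the line number."""
    records: list[IndividualRecord] = []
    seen_ids: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COHORT_COLUMNS:
            raise CohortParseError(f"line 1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_COHORT_COLUMNS):
                raise CohortParseError(
                    f"line {lineno}: expected {len(_COHORT_COLUMNS)} fields, "
                    f"got {len(parts)}"
                )
            row = dict(zip(_COHORT_COLUMNS, parts))
            if row["id"] in seen_ids:
                raise CohortParseError(f"line {lineno}: duplicate id {row['id']!r}")
            seen_ids.add(row["id"])
            if row["status"] not in ("0", "1"):
                raise CohortParseError(f"line {lineno}: bad status {row['status']!r}")
            if row["sex"] not in ("F", "M"):
                raise CohortParseError(f"line {lineno}: bad sex {row['sex']!r}")
            for locus_cols in (("A1", "A2"), ("B1", "B2"), ("C1", "C2"),
                               ("DRB1_1", "DRB1_2"), ("DQA1_1", "DQA1_2"),
                               ("DQB1_1", "DQB1_2")):
                for c in locus_cols:
                    if ";" in row[c]:
                        raise CohortParseError(
                            f"line {lineno}: more than 2 alleles at locus "
                            f"{c.rstrip('12_')}"
                        )
            genes = frozenset(g for g in row["kir_genes"].split(";") if g)
            records.append(
                IndividualRecord(
                    id=row["id"],
                    case_status="case" if row["status"] == "1" else "control",
                    sex=row["sex"],
                    kir_genes=genes,
                    hla_class1=(row["A1"], row["A2"], row["B1"], row["B2"],
                                row["C1"], row["C2"]),
                    hla_class2=(row["DRB1_1"], row["DRB1_2"], row["DQA1_1"],
                                row["DQA1_2"], row["DQB1_1"], row["DQB1_2"]),
                    hap1=row["hap1"], hap2=row["hap2"],
                )
            )
    return records


_TRIO_EXTRA = _COHORT_COLUMNS[3:]  # genotype columns shared with cohort table


def write_trios(trios: list[TrioRecord], path) -> None:
    """PED-like trio table: one row per person plus genotype columns.

    The child's hap1 is the transmitted paternal haplotype and hap2 the
    transmitted maternal haplotype, so transmission flags are recoverable.
    """
    cols = ["family_id", "person_id", "father_id", "mother_id", "sex",
            "affected"] + _TRIO_EXTRA
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")

        def person_row(fam, r, father_id, mother_id, affected):
            return [
                fam, r.id, father_id, mother_id, r.sex, str(affected),
                ";".join(sorted(r.kir_genes)), *r.hla_class1,
                r.hla_class2[0], r.hla_class2[1], r.hla_class2[2],
                r.hla_class2[3], r.hla_class2[4], r.hla_class2[5],
                r.hap1, r.hap2,
            ]

        for t in trios:
            fh.write("\t".join(person_row(t.family_id, t.father, "0", "0", 0)) + "\n")
            fh.write("\t".join(person_row(t.family_id, t.mother, "0", "0", 0)) + "\n")
            fh.write("\t".join(
                person_row(t.family_id, t.child, t.father.id, t.mother.id, 1)
            ) + "\n")


def read_trios(path) -> list[TrioRecord]:
    """Rebuild trio records; transmitted haplotypes are re-derived by matching
    the child's phased haplotypes against each parent's."""
    people: dict[str, dict] = {}
    order: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise CohortParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            row = dict(zip(header, parts))
            people[row["person_id"]] = row
            order.append(row["person_id"])

    def to_record(row, status) -> IndividualRecord:
        return IndividualRecord(
            id=row["person_id"], case_status=status, sex=row["sex"],
            kir_genes=frozenset(g for g in row["kir_genes"].split(";") if g),
            hla_class1=(row["A1"], row["A2"], row["B1"], row["B2"],
                        row["C1"], row["C2"]),
            hla_class2=(row["DRB1_1"], row["DRB1_2"], row["DQA1_1"],
                        row["DQA1_2"], row["DQB1_1"], row["DQB1_2"]),
            hap1=row["hap1"], hap2=row["hap2"],
        )

    trios = []
    for pid in order:
        row = people[pid]
        if row["affected"] != "1":
            continue
        father = people[row["father_id"]]
        mother = people[row["mother_id"]]
        child = to_record(row, "case")
        tf = 0 if father["hap1"] == row["hap1"] else 1
        tm = 0 if mother["hap1"] == row["hap2"] else 1
        trios.append(
            TrioRecord(
                family_id=row["family_id"],
                child=child,
                father=to_record(father, "control"),
                mother=to_record(mother, "control"),
                transmitted_father=tf,
                transmitted_mother=tm,
            )
        )
    return trios


# --- bespoke carriage-matrix generator for the driver screen -----------------


def generate_driver_cohort(
    n: int = 2000,
    n_noise: int = 8,
    causal_freq: float = 0.3,
    causal_effect: float = -1.5,
    passenger_r: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Case-control carriage matrix with one causal protective genotype, one
    linkage passenger at correlation ~``passenger_r`` and independent neutral
    noise genotypes.

    Returns a frame with columns ``status``, ``sex``, ``g_causal``,
    ``g_passenger``, ``g_noise0``..; genotype columns are 0/1 carriage.
    """
    rng = np.random.default_rng(seed)
    causal = rng.random(n) < causal_freq
    flip = rng.random(n) < (1.0 - passenger_r) / 2.0
    passenger = causal ^ flip
    noise = {
        f"g_noise{i}": rng.random(n) < rng.uniform(0.1, 0.4)
        for i in range(n_noise)
    }
    female = rng.random(n) < 0.5
    lp = causal_effect * causal + 0.2 * (~female)
    b0 = _solve_intercept(lp, 0.5)
    status = rng.random(n) < expit(b0 + lp)
    out = pd.DataFrame({
        "status": status.astype(int),
        "sex": np.where(female, "F", "M"),
        "g_causal": causal.astype(int),
        "g_passenger": passenger.astype(int),
    })
    for k, v in noise.items():
        out[k] = v.astype(int)
    return out
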