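"""Stratified transmission analysis for affected-child trios.

For each genotype, informative (heterozygous-by-carriage) parents are
classified by whether the genotype-bearing haplotype was transmitted to the
affected child; trios are stratified by the child's iKIR score.  The
statistic compares transmission log-ratios across strata:
``D = log(T/NT)_high - log(T/NT)_low``; for a protective genotype under
iKIR modification the under-transmission is weaker in the high stratum, so
D > 0.  Its null distribution is built by permuting the children's iKIR
scores across trios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .permutation import PermutationResult
from .syndata import TrioRecord

log = logging.getLogger(__name__)


class ZeroCellError(ValueError):
    pass


@dataclass
class TransmissionTable:
    genotype: str
    threshold: float
    t_high: int = 0
    nt_high: int = 0
    t_low: int = 0
    nt_low: int = 0
    n_informative_parents: int = 0
    n_uninformative_parents: int = 0

    def counts(self, stratum: str) -> tuple[int, int]:
        if stratum == "high":
            return self.t_high, self.nt_high
        return self.t_low, self.nt_low


def _hap_carries(hap: str, genotype_label: str) -> bool:
    parts = set(hap.split("|")) if hap else set()
    return all(a in parts for a in genotype_label.split("-"))


def _per_trio_counts(
    trios: list[TrioRecord], genotype_label: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """(t, nt) transmission counts per trio plus the uninformative-parent
    count.  A parent is informative iff exactly one of its two haplotypes
    carries the genotype."""
    t = np.zeros(len(trios), dtype=float)
    nt = np.zeros(len(trios), dtype=float)
    uninformative = 0
    for i, trio in enumerate(trios):
        for parent, trans in (
            (trio.father, trio.transmitted_father),
            (trio.mother, trio.transmitted_mother),
        ):
            haps = (parent.hap1, parent.hap2)
            carry = [_hap_carries(h, genotype_label) for h in haps]
            if sum(carry) != 1:
                uninformative += 1
                continue
            carrier_idx = carry.index(True)
            if trans == carrier_idx:
                t[i] += 1
            else:
                nt[i] += 1
    return t, nt, uninformative


def child_scores(trios: list[TrioRecord]) -> np.ndarray:
    return np.asarray([t.child.score for t in trios], dtype=float)


def transmission_counts(
    trios: list[TrioRecord],
    genotype: str,
    threshold: float = 1.75,
    scores: np.ndarray | None = None,
) -> TransmissionTable:
    """Transmission / non-transmission counts per iKIR stratum.

    Stratum assignment uses only the affected child's score (ties at the
    threshold go to "low").  Uninformative parents are excluded and counted.
    """
    label = genotype if isinstance(genotype, str) else genotype.label
    t, nt, uninf = _per_trio_counts(trios, label)
    s = child_scores(trios) if scores is None else np.asarray(scores, float)
    high = s > threshold
    table = TransmissionTable(
        genotype=label,
        threshold=threshold,
        t_high=int(t[high].sum()),
        nt_high=int(nt[high].sum()),
        t_low=int(t[~high].sum()),
        nt_low=int(nt[~high].sum()),
        n_informative_parents=int((t + nt).sum()),
        n_uninformative_parents=uninf,
    )
    if uninf:
        log.info("%s: %d uninformative parents excluded", label, uninf)
    return table


def strata_difference_stat(
    table: TransmissionTable, continuity: bool = True, form: str = "log"
) -> float:
    """``log(T/NT)_high - log(T/NT)_low`` (default) or the raw-ratio
    difference.  With ``continuity`` the Haldane +0.5 is added to every cell
    whenever any cell is zero; otherwise zero cells raise."""
    cells = [table.t_high, table.nt_high, table.t_low, table.nt_low]
    if any(c == 0 for c in cells):
        if not continuity:
            raise ZeroCellError(f"zero transmission cell in {table.genotype}")
        cells = [c + 0.5 for c in cells]
    th, nth, tl, ntl = cells
    if form == "log":
        return math.log(th / nth) - math.log(tl / ntl)
    if form == "ratio":
        return th / nth - tl / ntl
    raise ValueError(f"unknown form {form!r}")


def _aggregate_stat(
    t_mat: np.ndarray,
    nt_mat: np.ndarray,
    high: np.ndarray,
    weights: np.ndarray,
    form: str = "log",
) -> np.ndarray:
    """Carriage-frequency-weighted mean of per-genotype D, vectorised over
    stratum assignments.  high: (P, n_trios); t_mat/nt_mat: (n_trios, G)."""
    high = np.atleast_2d(high).astype(float)
    th = high @ t_mat + 0.5
    nth = high @ nt_mat + 0.5
    tl = (t_mat.sum(axis=0)[None, :] - (th - 0.5)) + 0.5
    ntl = (nt_mat.sum(axis=0)[None, :] - (nth - 0.5)) + 0.5
    if form == "log":
        d = np.log(th / nth) - np.log(tl / ntl)
    else:
        d = th / nth - tl / ntl
    return (d * weights).sum(axis=1) / weights.sum()


def tdt_permutation_test(
    trios: list[TrioRecord],
    genotypes: list[str],
    threshold: float = 1.75,
    n_perm: int = 100_000,
    seed: int = 0,
    direction: str = "greater",
    form: str = "log",
) -> PermutationResult:
    """Permutation p for the cross-strata transmission difference.

    The null permutes the affected children's iKIR scores across trios;
    parental data are untouched.  Multiple genotypes aggregate as the
    carriage-frequency-weighted mean of per-genotype D (reducing to D itself
    for a single genotype); p uses the add-one rule.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = [g if isinstance(g, str) else g.label for g in genotypes]
    t_cols, nt_cols, weights = [], [], []
    for label in labels:
        t, nt, _ = _per_trio_counts(trios, label)
        t_cols.append(t)
        nt_cols.append(nt)
        child_carr = np.mean([
            _hap_carries(tr.child.hap1, label) or _hap_carries(tr.child.hap2, label)
            for tr in trios
        ])
        weights.append(max(child_carr, 1.0 / (2 * len(trios))))
    t_mat = np.column_stack(t_cols)
    nt_mat = np.column_stack(nt_cols)
    w = np.asarray(weights)

    scores = child_scores(trios)
    high_obs = scores > threshold
    if not high_obs.any() or high_obs.all():
        raise ValueError("both strata must be non-empty")
    obs = float(_aggregate_stat(t_mat, nt_mat, high_obs[None, :], w, form)[0])

    rng = np.random.default_rng(seed)
    perm = np.tile(scores, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    null = _aggregate_stat(t_mat, nt_mat, perm > threshold, w, form)

    if direction == "greater":
        extreme = int((null >= obs).sum())
    elif direction == "less":
        extreme = int((null <= obs).sum())
    else:
        extreme = int((np.abs(null) >= abs(obs)).sum())
    p = (extreme + 1) / (n_perm + 1)
    return PermutationResult(
        observed_stat=obs, n_perm=n_perm, n_as_extreme=extreme, p_value=p,
        direction=direction, seed=seed,
        weights=dict(zip(labels, w)), statistic=f"tdt-{form}",
    )
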