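"""Driver-genotype screen: exhaustive pairwise co-regression, the effective
number of tests, and Bonferroni-adjusted significance.

A genotype is a *driver* if its sex-adjusted coefficient keeps its direction
and stays significant when co-fitted with every other enumerated genotype in
turn.  Because HLA genotypes are heavily correlated, multiplicity is
corrected with an effective number of tests (Li & Ji eigenvalue method on
the carriage-indicator correlation matrix) rather than the raw count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association
from .genotypes import (
    CLASS1_COLUMNS,
    CLASS2_COLUMNS,
    GenotypeDef,
    carriage,
)

log = logging.getLogger(__name__)


@dataclass
class DriverCall:
    genotype: str
    is_driver: bool
    ln_or: float
    p_value: float
    n_carriers: int
    failing_partner: str | None = None
    reason: str = ""


def pairwise_combinations(m: int) -> int:
    """Number of unordered genotype pairs, m(m-1)/2."""
    return m * (m - 1) // 2


def enumerate_genotypes(
    df: pd.DataFrame,
    max_alleles: int = 3,
    min_carriage: int = 20,
) -> list[GenotypeDef]:
    """Deduplicated canonical genotype list with a minimum-carriage filter.

    Enumerates every class I allele, every class II allele, and every 2- and
    3-allele class II combination observed within at least one individual
    (cis or trans), i.e. candidate genotypes that could plausibly be carried.
    """
    class1 = set()
    for cols in CLASS1_COLUMNS.values():
        for c in cols:
            class1.update(a for a in df[c].unique() if isinstance(a, str) and a)
    defs: dict[str, GenotypeDef] = {}
    for a in sorted(class1):
        g = GenotypeDef((a,))
        defs[g.label] = g

    c2cols = [c for cols in CLASS2_COLUMNS.values() for c in cols]
    combo_counts: dict[tuple[str, ...], int] = {}
    for _, row in df[c2cols].iterrows():
        alleles = sorted({a for a in row if isinstance(a, str) and a})
        for k in range(1, min(max_alleles, 3) + 1):
            for combo in itertools.combinations(alleles, k):
                loci = [a.split("*", 1)[0] for a in combo]
                if any(loci.count(l) > 2 for l in set(loci)):
                    continue
                combo_counts[combo] = combo_counts.get(combo, 0) + 1
    for combo, cnt in combo_counts.items():
        if cnt < min_carriage:
            continue
        g = GenotypeDef(tuple(combo))
        defs.setdefault(g.label, g)

    out = []
    for label in sorted(defs):
        g = defs[label]
        n = int(carriage(df, g).sum())
        if n >= min_carriage:
            out.append(g)
    log.info("enumerated %d genotypes (m(m-1)/2 = %d pairs)",
             len(out), pairwise_combinations(len(out)))
    return out


def _carriage_matrix(df: pd.DataFrame, genotypes) -> tuple[np.ndarray, list[str]]:
    labels = []
    cols = []
    for g in genotypes:
        if isinstance(g, str) and g in df.columns:
            cols.append(df[g].to_numpy(dtype=float))
            labels.append(g)
        else:
            gd = GenotypeDef.parse(g) if isinstance(g, str) else g
            cols.append(carriage(df, gd).astype(float))
            labels.append(gd.label)
    return np.column_stack(cols), labels


def pairwise_driver_screen(
    df: pd.DataFrame,
    genotypes: list,
    alpha_retain: float = 0.05,
    collinearity_r: float = 0.99,
) -> list[DriverCall]:
    """Call drivers by pairwise co-regression.

    ``genotypes`` may be :class:`GenotypeDef` objects, genotype labels, or
    names of 0/1 columns already present in ``df``.  For each ordered pair
    the model ``status ~ g + h + male`` is fitted once; a genotype fails if
    its coefficient loses significance (p >= alpha_retain) or flips sign
    relative to its marginal sex-adjusted estimate.  Pairs with
    |r| >= ``collinearity_r`` are not co-fitted: the member with the larger
    marginal p is excluded in favour of the other (logged).  Output order is
    deterministic (input order) and independent of pair visit order.
    """
    X, labels = _carriage_matrix(df, genotypes)
    y = df["status"].to_numpy(dtype=float)
    male = (df["sex"] == "M").astype(float).to_numpy()
    m = len(labels)

    marginal: dict[str, association.AssocResult] = {}
    for j, lab in enumerate(labels):
        Xj = pd.DataFrame({"g": X[:, j], "male": male})
        marginal[lab] = association.fit_logistic(y, Xj)["g"]

    failing: dict[str, tuple[str, str]] = {}  # label -> (partner, reason)
    corr = np.corrcoef(X, rowvar=False) if m > 1 else np.ones((1, 1))
    for j, k in itertools.combinations(range(m), 2):
        gj, gk = labels[j], labels[k]
        r = corr[j, k]
        if abs(r) >= collinearity_r:
            # simplifying rule for (near-)collinear pairs: keep the one with
            # the smaller marginal p, exclude the other
            drop, keep = (gj, gk) if marginal[gj].p_value > marginal[gk].p_value else (gk, gj)
            log.warning("collinear pair |r|=%.3f: excluding %s in favour of %s",
                        abs(r), drop, keep)
            failing.setdefault(drop, (keep, f"collinear (|r|={abs(r):.3f})"))
            continue
        Xp = pd.DataFrame({"gj": X[:, j], "gk": X[:, k], "male": male})
        try:
            fit = association.fit_logistic(y, Xp)
        except association.SeparationError as exc:
            log.warning("pair (%s, %s) inestimable: %s", gj, gk, exc)
            failing.setdefault(gj, (gk, "pair fit inestimable"))
            failing.setdefault(gk, (gj, "pair fit inestimable"))
            continue
        for lab, term in ((gj, "gj"), (gk, "gk")):
            res = fit[term]
            if res.p_value >= alpha_retain:
                failing.setdefault(lab, (gk if lab == gj else gj, "lost significance"))
            elif np.sign(res.ln_or) != np.sign(marginal[lab].ln_or):
                failing.setdefault(lab, (gk if lab == gj else gj, "sign flip"))

    calls = []
    for j, lab in enumerate(labels):
        mres = marginal[lab]
        marginally_ok = mres.p_value < alpha_retain
        fail = failing.get(lab)
        is_driver = marginally_ok and fail is None
        calls.append(
            DriverCall(
                genotype=lab,
                is_driver=is_driver,
                ln_or=mres.ln_or,
                p_value=mres.p_value,
                n_carriers=int(X[:, j].sum()),
                failing_partner=None if is_driver else (fail[0] if fail else None),
                reason="" if is_driver else (
                    fail[1] if fail else "not marginally significant"
                ),
            )
        )
    return calls


def effective_tests(carriage_matrix: np.ndarray | pd.DataFrame) -> float:
    """Li & Ji effective number of tests from the carriage correlation matrix.

    Constant columns are dropped with a warning.  Satisfies
    1 <= Meff <= m, with Meff = m for independent indicators and Meff = 1
    when all columns are perfectly correlated.
    """
    X = np.asarray(carriage_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with >= 2 genotype columns")
    keep = X.std(axis=0) > 0
    if not keep.all():
        log.warning("dropping %d constant genotype columns", int((~keep).sum()))
        X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant genotype columns")
    R = np.corrcoef(X, rowvar=False)
    return meff_from_correlation(R)


def meff_from_correlation(R: np.ndarray) -> float:
    """Li & Ji estimator: Meff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ]."""
    R = np.asarray(R, dtype=float)
    lam = np.linalg.eigvalsh(R)
    # guard the floor against eigenvalues a few ulp off an integer
    lam = np.round(np.clip(lam, 0.0, None), 9)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def adjusted_threshold(alpha: float, meff: float) -> float:
    """Bonferroni cutoff alpha / Meff."""
    if meff < 1:
        raise ValueError("Meff must be >= 1")
    return alpha / meff


def screen_to_frame(calls: list[DriverCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genotype": [c.genotype for c in calls],
            "is_driver": [c.is_driver for c in calls],
            "ln_or": [c.ln_or for c in calls],
            "p_value": [c.p_value for c in calls],
            "n_carriers": [c.n_carriers for c in calls],
            "failing_partner": [c.failing_partner for c in calls],
            "reason": [c.reason for c in calls],
        }
    )
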