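"""Population impact of iKIR-score modification of a protective genotype.

Translates stratum-specific odds ratios into a prevented fraction of cases
under counterfactual all-high / all-low score scenarios, the relative change
between scenarios, and a "SNP-scale" odds ratio for the [0,1]-normalised
iKIR score within genotype-positive individuals.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from . import association, kir_core
from .genotypes import carriage

log = logging.getLogger(__name__)


def or_to_rr(odds_ratio: float, p0: float) -> float:
    """Convert an odds ratio to a risk ratio given the unexposed
    (genotype-negative) risk ``p0``: RR = OR / (1 - p0 + p0*OR)."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be > 0")
    if not 0 < p0 < 1:
        raise ValueError("baseline risk must be in (0,1)")
    return odds_ratio / (1.0 - p0 + p0 * odds_ratio)


def prevented_fraction(
    genotype_freq: float,
    relative_risk: float | None = None,
    odds_ratio: float | None = None,
    prevalence: float | None = None,
) -> float:
    """PF = f * (1 - RR): fraction of cases averted by carriage of a
    protective genotype relative to the genotype-absent counterfactual.

    Either pass ``relative_risk`` directly, or an ``odds_ratio`` plus the
    disease ``prevalence`` (the non-carrier risk is then derived from the
    prevalence and the OR is converted to an RR).  RR > 1 yields a negative
    value (excess, not prevention) with a warning.
    """
    if not 0.0 <= genotype_freq <= 1.0:
        raise ValueError("genotype frequency must be in [0,1]")
    if relative_risk is None:
        if odds_ratio is None or prevalence is None:
            raise ValueError("need relative_risk, or odds_ratio + prevalence")
        # prevalence = (1-f) p0 + f p1 with p1 = p0*OR/(1-p0+p0*OR); solve p0
        from scipy.optimize import brentq

        def g(p0):
            p1 = p0 * odds_ratio / (1 - p0 + p0 * odds_ratio)
            return (1 - genotype_freq) * p0 + genotype_freq * p1 - prevalence

        p0 = brentq(g, 1e-12, 1 - 1e-12)
        relative_risk = or_to_rr(odds_ratio, p0)
    if relative_risk <= 0:
        raise ValueError("relative risk must be > 0")
    pf = genotype_freq * (1.0 - relative_risk)
    if pf < 0:
        warnings.warn("RR > 1: returning a negative (excess) fraction")
    return pf


def relative_increase(pf_low: float, pf_high: float) -> float:
    """Percent increase of the all-low-score scenario over the all-high one:
    100 * (pf_low - pf_high) / pf_high."""
    if pf_high <= 0:
        raise ValueError("pf_high must be > 0")
    return 100.0 * (pf_low - pf_high) / pf_high


def normalized_score_or(
    df: pd.DataFrame,
    genotype,
    score_col: str = "score",
    weights: kir_core.ScoreWeights | None = None,
    adjust_sex: bool = True,
) -> association.AssocResult:
    """OR per full sweep of the [0,1]-normalised iKIR score among
    genotype-positive individuals.

    The score is min-max rescaled over its *attainable* range (from the
    weight table), putting it on the presence/absence scale of a SNP.  A
    constant score in the subcohort is an error.
    """
    weights = weights or kir_core.ScoreWeights.default()
    lo, hi = weights.attainable_range()
    sub = df[np.asarray(carriage(df, genotype), dtype=bool)]
    if sub["status"].nunique() < 2:
        raise ValueError("genotype-positive subcohort needs cases and controls")
    s = sub[score_col].to_numpy(dtype=float)
    if s.min() == s.max():
        raise ValueError("score is constant in the subcohort")
    X = pd.DataFrame({"score_norm": (s - lo) / (hi - lo)}, index=sub.index)
    if adjust_sex:
        X["male"] = (sub["sex"] == "M").astype(float)
    res = association.fit_logistic(sub["status"], X)["score_norm"]
    res.n = len(sub)
    return res


def impact_summary(
    df: pd.DataFrame,
    genotype,
    prevalence: float,
    threshold: float = 1.75,
    min_cases: int = 10,
) -> dict:
    """Prevented fractions under all-high / all-low scenarios plus the
    normalised-score OR, from stratum-specific estimates in one cohort."""
    hi, lo = association.stratified_effect(
        df, genotype, threshold=threshold, min_cases=min_cases
    )
    f = float(np.asarray(carriage(df, genotype), dtype=float).mean())
    pf_high = prevented_fraction(
        f, odds_ratio=math.exp(hi.ln_or), prevalence=prevalence
    )
    pf_low = prevented_fraction(
        f, odds_ratio=math.exp(lo.ln_or), prevalence=prevalence
    )
    out = {
        "genotype_freq": f,
        "pf_all_high_pct": 100 * pf_high,
        "pf_all_low_pct": 100 * pf_low,
        "relative_increase_pct": relative_increase(100 * pf_low, 100 * pf_high),
    }
    try:
        res = normalized_score_or(df, genotype)
        out["normalized_score_or"] = math.exp(res.ln_or)
        out["normalized_score_or_ci"] = (
            math.exp(res.ci_low), math.exp(res.ci_high)
        )
    except (ValueError, association.SeparationError) as exc:
        log.warning("normalised-score OR unavailable: %s", exc)
    return out
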