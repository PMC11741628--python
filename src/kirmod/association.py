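"""Maximum-likelihood logistic association analysis.

Crude and covariate-adjusted ln[OR]s, stratum-specific effects, continuous
and stratified score-interaction models with AIC comparison, and a
resampling-based power analysis.  Estimates are Wald-based throughout
(coefficient, 95% CI, p-value); a single binary predictor with no covariates
reproduces the closed-form 2x2 crude ln[OR] exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeDef, carriage

log = logging.getLogger(__name__)


class ZeroCellError(ValueError):
    """A 2x2 cell is zero and no continuity correction was requested."""


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation in a logistic fit."""


class GenotypeSkipped(ValueError):
    """Genotype excluded by the minimum case-carrier filter."""


@dataclass
class AssocResult:
    term: str
    ln_or: float
    ci_low: float
    ci_high: float
    p_value: float
    n_by_cell: tuple[int, int, int, int] | None = None  # (a, b, c, d)
    model_formula: str = ""
    stratum: str = "whole"  # high | low | whole
    aic: float = float("nan")
    n: int = 0

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.ln_or)


def crude_ln_or(a: int, b: int, c: int, d: int, continuity: bool = False) -> float:
    """ln[(a*d)/(b*c)] for a 2x2 carriage-by-status table.

    a = genotype+ cases, b = genotype+ controls, c = genotype- cases,
    d = genotype- controls.  Zero cells raise unless the Haldane-Anscombe
    +0.5 correction is explicitly enabled.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if any(x == 0 for x in cells):
        if not continuity:
            raise ZeroCellError(
                f"zero cell in 2x2 table {cells}; enable continuity correction"
            )
        a, b, c, d = (x + 0.5 for x in cells)
    return math.log((a * d) / (b * c))


def crude_ln_or_ci(
    a: int, b: int, c: int, d: int, continuity: bool = False, level: float = 0.95
) -> tuple[float, float, float]:
    """(ln_or, lo, hi) with the Woolf (delta-method) standard error."""
    lnor = crude_ln_or(a, b, c, d, continuity=continuity)
    cells = [a, b, c, d]
    if continuity and any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
    se = math.sqrt(sum(1.0 / x for x in cells))
    z = stats.norm.ppf(0.5 + level / 2)
    return lnor, lnor - z * se, lnor + z * se


def _check_fit(res, X: pd.DataFrame) -> None:
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        raise SeparationError("non-finite estimates: likely separation")
    if np.any(np.abs(params) > 30) or np.any(bse > 200):
        raise SeparationError(
            "diverging estimates: perfect or quasi-perfect separation"
        )


def fit_logistic(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    add_const: bool = True,
    start_params: np.ndarray | None = None,
) -> dict[str, AssocResult]:
    """ML logistic fit; returns one Wald :class:`AssocResult` per column of X.

    Raises :class:`SeparationError` instead of silently returning a diverged
    fit, and requires at least one case and one control.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    design = sm.add_constant(X, has_constant="add") if add_const else X
    try:
        model = sm.Logit(y, design.astype(float))
        res = model.fit(disp=0, start_params=start_params, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise SeparationError(str(exc)) from exc
    _check_fit(res, design)
    ci = res.conf_int()
    formula = "status ~ " + " + ".join(X.columns)
    out: dict[str, AssocResult] = {}
    for term in X.columns:
        out[term] = AssocResult(
            term=term,
            ln_or=float(res.params[term]),
            ci_low=float(ci.loc[term, 0]),
            ci_high=float(ci.loc[term, 1]),
            p_value=float(res.pvalues[term]),
            model_formula=formula,
            aic=float(res.aic),
            n=len(y),
        )
    return out


def _sex_indicator(df: pd.DataFrame) -> pd.Series:
    return (df["sex"] == "M").astype(float).rename("male")


def two_by_two(df: pd.DataFrame, carrier: np.ndarray) -> tuple[int, int, int, int]:
    status = df["status"].to_numpy().astype(bool)
    carrier = np.asarray(carrier, dtype=bool)
    a = int((carrier & status).sum())
    b = int((carrier & ~status).sum())
    c = int((~carrier & status).sum())
    d = int((~carrier & ~status).sum())
    return a, b, c, d


def genotype_effect(
    df: pd.DataFrame,
    genotype: GenotypeDef | str,
    adjust_sex: bool = True,
    adjust_ligands: bool = False,
) -> AssocResult:
    """Sex-adjusted (optionally ligand-adjusted) carriage effect in a cohort."""
    carr = carriage(df, genotype)
    X = pd.DataFrame({"genotype": carr.astype(float)}, index=df.index)
    if adjust_sex:
        X["male"] = _sex_indicator(df)
    if adjust_ligands:
        for c in ("lig_bw4", "lig_c1", "lig_c2"):
            X[c] = df[c].astype(float)
    res = fit_logistic(df["status"], X)["genotype"]
    res.n_by_cell = two_by_two(df, carr)
    return res


def stratified_effect(
    df: pd.DataFrame,
    genotype: GenotypeDef | str,
    threshold: float = 1.75,
    adjust_ligands: bool = False,
    min_cases: int = 10,
    score_col: str = "score",
) -> tuple[AssocResult, AssocResult]:
    """Independent sex-adjusted fits in the high and low iKIR-score strata.

    Genotypes carried by fewer than ``min_cases`` cases overall are skipped
    (raises :class:`GenotypeSkipped`); ties at the threshold go to "low".
    """
    carr = np.asarray(carriage(df, genotype), dtype=bool)
    n_case_carriers = int((carr & (df["status"] == 1)).sum())
    if n_case_carriers < min_cases:
        raise GenotypeSkipped(
            f"{genotype}: only {n_case_carriers} case carriers (< {min_cases})"
        )
    high = df[score_col].to_numpy() > threshold
    out = []
    for name, mask in (("high", high), ("low", ~high)):
        sub = df[mask]
        res = genotype_effect(sub, genotype, adjust_ligands=adjust_ligands)
        res.stratum = name
        out.append(res)
    return out[0], out[1]


def interaction_model(
    df: pd.DataFrame,
    genotype: GenotypeDef | str,
    score_mode: str = "continuous",  # continuous | stratified
    threshold: float = 1.75,
    score_col: str = "score",
) -> AssocResult:
    """Whole-cohort model with a genotype-by-score interaction term.

    ``continuous`` uses the raw score; ``stratified`` replaces it with the
    high-stratum indicator.  The returned result is for the interaction term
    and carries the model AIC (= 2k - 2 max log-likelihood).
    """
    carr = np.asarray(carriage(df, genotype), dtype=float)
    if score_mode == "continuous":
        score = df[score_col].to_numpy(dtype=float)
    elif score_mode == "stratified":
        score = (df[score_col].to_numpy() > threshold).astype(float)
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")
    X = pd.DataFrame(
        {
            "genotype": carr,
            "score": score,
            "genotype_x_score": carr * score,
            "male": _sex_indicator(df),
        },
        index=df.index,
    )
    res = fit_logistic(df["status"], X)["genotype_x_score"]
    res.n_by_cell = two_by_two(df, carr.astype(bool))
    return res


def stepwise_score_vs_count(
    df: pd.DataFrame,
    genotype: GenotypeDef | str,
    score_col: str = "score",
    count_col: str = "count",
) -> str:
    """Backward step from a model with both standardised interaction terms.

    Drops whichever of the score / count interaction removes with the lower
    AIC; returns the name of the retained variable ("score" or "count").
    """
    carr = np.asarray(carriage(df, genotype), dtype=float)
    z = lambda v: (v - v.mean()) / v.std()
    score = z(df[score_col].to_numpy(dtype=float))
    count = z(df[count_col].to_numpy(dtype=float))
    male = _sex_indicator(df)
    y = df["status"]

    def aic_without(drop: str) -> float:
        cols = {"genotype": carr, "male": male}
        keep = "count" if drop == "score" else "score"
        v = count if keep == "count" else score
        cols[keep] = v
        cols[f"genotype_x_{keep}"] = carr * v
        return fit_logistic(y, pd.DataFrame(cols, index=df.index))["genotype"].aic

    return "score" if aic_without("count") <= aic_without("score") else "count"


def power_by_resampling(
    df: pd.DataFrame,
    genotype: GenotypeDef | str,
    sample_sizes: list[int],
    n_boot: int = 1000,
    alpha: float = 0.05,
    threshold: float = 1.75,
    score_mode: str = "stratified",
    seed: int = 0,
) -> dict[int, float]:
    """Power of the genotype-by-score interaction at each subcohort size.

    For each size ``s`` (cases = controls = s/2) draws ``n_boot`` subcohorts
    by resampling with replacement and reports the fraction with interaction
    p < ``alpha``.  Inestimable resamples (separation) count as non-rejections.
    """
    rng = np.random.default_rng(seed)
    cases = df[df["status"] == 1]
    controls = df[df["status"] == 0]
    out: dict[int, float] = {}
    for s in sample_sizes:
        if s % 2:
            raise ValueError("sample size must be even (cases = controls = s/2)")
        hits = 0
        for _ in range(n_boot):
            sub = pd.concat(
                [
                    cases.sample(s // 2, replace=True, random_state=rng.integers(2**31)),
                    controls.sample(s // 2, replace=True, random_state=rng.integers(2**31)),
                ],
                ignore_index=True,
            )
            try:
                res = interaction_model(
                    sub, genotype, score_mode=score_mode, threshold=threshold
                )
            except (SeparationError, ValueError):
                continue
            hits += res.p_value < alpha
        out[s] = hits / n_boot
    return out
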