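"""ODE model of autoimmune beta-cell destruction with Treg regulation.

State: beta-cell mass ``B``, islet-autoreactive conventional T cells ``E``
(Tconv) and regulatory T cells ``R`` (Treg).

    dB/dt = -kappa * E * B / (1 + q * R)
    dE/dt = sigma_e + rho_e * E * B/(s + B) * g - delta_e * E
    dR/dt = sigma_r + rho_r * R * B/(s + B) * g - delta_r * R

with ``g = 1`` (model 1, no density dependence) or ``g = 1 - (E + R)/K``
(model 2, shared carrying capacity on T-cell production).  Tconvs kill
beta-cells, Tregs suppress the killing; antigen (B) drives proliferation of
both with half-saturation ``s``.  A high functional-iKIR genotype extends
T-cell survival: the "high" arm multiplies both death rates by (1 - eps).
An individual develops T1D when the final beta-cell fraction falls below
the onset threshold ``theta``.  High Treg supply ``sigma_r`` is the proxy
for a protective HLA class II genotype (it drives Treg numbers toward the
carrying capacity, where the extra survival benefits Tconvs only).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelParams:
    beta0: float = 1.0       # initial beta-cell mass (normalised)
    kappa: float = 0.5       # killing rate per Tconv
    sigma_e: float = 0.02    # Tconv thymic/priming source
    rho_e: float = 1.0       # Tconv antigen-driven proliferation
    sigma_r: float = 0.02    # Treg source (HLA-protection proxy)
    rho_r: float = 1.0       # Treg antigen-driven proliferation
    q: float = 1.0           # Treg suppression strength
    delta_e: float = 0.5     # Tconv death rate
    delta_r: float = 0.5     # Treg death rate
    K: float = math.inf      # carrying capacity (model 2); inf = model 1
    s: float = 0.3           # antigen half-saturation
    epsilon: float = 0.35    # iKIR death-rate multiplier, in [0,1)
    t_end: float = 25.0
    theta: float = 0.1       # onset threshold on final beta fraction

    def validate(self) -> None:
        for name in ("beta0", "kappa", "sigma_e", "rho_e", "sigma_r",
                     "rho_r", "q", "delta_e", "delta_r", "s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must be in [0,1)")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0,1)")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")


@dataclass
class SimulationResult:
    t: np.ndarray
    B: np.ndarray
    E: np.ndarray
    R: np.ndarray
    outcome: str              # "T1D" | "healthy"
    final_beta_fraction: float
    mean_treg: float
    peak_treg: float = 0.0
    success: bool = True


class IntegrationError(RuntimeError):
    pass


def simulate_individual(
    params: ModelParams,
    model: int = 2,
    ikir_arm: str = "low",
    n_eval: int = 201,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    y0: tuple[float, float, float] | None = None,
) -> SimulationResult:
    """Integrate one individual's islet response in one iKIR arm.

    The "high" arm multiplies ``delta_e`` and ``delta_r`` by
    ``1 - epsilon`` (longer T-cell survival); model 1 is recovered from
    model 2 in the limit K -> inf.
    """
    params.validate()
    if ikir_arm not in ("high", "low"):
        raise ValueError(f"bad ikir_arm {ikir_arm!r}")
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    de, dr = params.delta_e, params.delta_r
    if ikir_arm == "high":
        de *= 1.0 - params.epsilon
        dr *= 1.0 - params.epsilon
    K = params.K if model == 2 else math.inf

    # pre-response homeostasis: source/death balance with no antigen drive
    if y0 is None:
        e0 = params.sigma_e / de if de > 0 else 0.0
        r0 = params.sigma_r / dr if dr > 0 else 0.0
        y0 = (params.beta0, e0, r0)

    def rhs(_t, y):
        B, E, R = np.maximum(y, 0.0)
        drive = B / (params.s + B)
        g = 1.0 if not np.isfinite(K) else 1.0 - (E + R) / K
        dB = -params.kappa * E * B / (1.0 + params.q * R)
        dE = params.sigma_e + params.rho_e * E * drive * g - de * E
        dR = params.sigma_r + params.rho_r * R * drive * g - dr * R
        return (dB, dE, dR)

    t_eval = np.linspace(0.0, params.t_end, n_eval)
    sol = solve_ivp(
        rhs, (0.0, params.t_end), y0,
        method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message)
    B, E, R = (np.maximum(sol.y[i], 0.0) for i in range(3))
    frac = float(B[-1] / params.beta0) if params.beta0 > 0 else 1.0
    return SimulationResult(
        t=sol.t, B=B, E=E, R=R,
        outcome="T1D" if frac < params.theta else "healthy",
        final_beta_fraction=frac,
        mean_treg=float(np.trapezoid(R, sol.t) / params.t_end),
        peak_treg=float(R.max()),
    )


@dataclass
class InSilicoIndividual:
    params: ModelParams
    outcome_high: str
    outcome_low: str
    mean_treg: float
    final_beta_high: float
    final_beta_low: float
    peak_treg: float = 0.0

    @property
    def arm_dependent(self) -> bool:
        return self.outcome_high != self.outcome_low


#: log-uniform sampling ranges for the in-silico cohort (per-parameter
#: [low, high]); values outside the dict are held at ModelParams defaults
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "kappa": (2.0, 20.0),
    "sigma_e": (0.02, 0.3),
    "rho_e": (0.2, 1.0),
    "sigma_r": (0.02, 0.3),
    "rho_r": (1.0, 6.0),
    "q": (0.5, 3.0),
    "delta_e": (0.2, 1.0),
    "delta_r": (0.2, 1.0),
}

DEFAULT_K: float = 10.0  # shared T-cell carrying capacity in model 2


def sample_params(
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
    K: float | None = None,
    **fixed,
) -> ModelParams:
    """One log-uniformly sampled parameter vector."""
    ranges = DEFAULT_RANGES if ranges is None else ranges
    draw = {}
    for name, (lo, hi) in ranges.items():
        if not (0 < lo <= hi) or not np.isfinite(hi):
            raise ValueError(f"range for {name} must be finite and positive")
        draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if K is not None:
        draw["K"] = K
    draw.update(fixed)
    return replace(ModelParams(), **draw)


def run_cohort(
    n: int = 10_000,
    seed: int = 0,
    model: int = 2,
    ranges: dict[str, tuple[float, float]] | None = None,
    K: float = DEFAULT_K,
    epsilon: float | None = None,
    max_failure_fraction: float = 0.05,
) -> list[InSilicoIndividual]:
    """Paired high/low-iKIR simulations over a sampled in-silico cohort.

    Each individual is one parameter draw simulated in both arms;
    ``mean_treg`` averages the Treg time-average over the two arms.
    Individuals whose integration fails are excluded (aborts if more than
    ``max_failure_fraction`` fail).
    """
    rng = np.random.default_rng(seed)
    out: list[InSilicoIndividual] = []
    failures = 0
    for _ in range(n):
        fixed = {} if epsilon is None else {"epsilon": epsilon}
        p = sample_params(rng, ranges, K=K if model == 2 else None, **fixed)
        try:
            hi = simulate_individual(p, model=model, ikir_arm="high")
            lo = simulate_individual(p, model=model, ikir_arm="low")
        except IntegrationError as exc:
            failures += 1
            log.warning("integration failure: %s", exc)
            continue
        out.append(
            InSilicoIndividual(
                params=p,
                outcome_high=hi.outcome,
                outcome_low=lo.outcome,
                mean_treg=0.5 * (hi.mean_treg + lo.mean_treg),
                final_beta_high=hi.final_beta_fraction,
                final_beta_low=lo.final_beta_fraction,
                peak_treg=max(hi.peak_treg, lo.peak_treg),
            )
        )
    if failures > max_failure_fraction * n:
        raise IntegrationError(
            f"{failures}/{n} integrations failed (> {max_failure_fraction:.0%})"
        )
    return out


def outcome_classes(cohort: list[InSilicoIndividual]) -> dict[str, int]:
    """Counts of always-healthy, always-T1D and arm-dependent individuals."""
    out = {"always_healthy": 0, "always_t1d": 0, "arm_dependent": 0}
    for ind in cohort:
        if ind.arm_dependent:
            out["arm_dependent"] += 1
        elif ind.outcome_high == "T1D":
            out["always_t1d"] += 1
        else:
            out["always_healthy"] += 1
    return out


def treg_binned_delta_lnor(
    cohort: list[InSilicoIndividual], n_bins: int = 10
) -> np.ndarray:
    """Per-Treg-bin difference of log-odds of T1D between the iKIR arms.

    Individuals are grouped into ``n_bins`` quantile bins of mean Treg
    number; per bin, ``delta = ln odds(T1D | high arm) - ln odds(T1D | low
    arm)`` with the Haldane +0.5 correction.  Empty/degenerate bins come
    back NaN, never silently dropped.
    """
    treg = np.asarray([c.mean_treg for c in cohort])
    hi = np.asarray([c.outcome_high == "T1D" for c in cohort], dtype=float)
    lo = np.asarray([c.outcome_low == "T1D" for c in cohort], dtype=float)
    edges = np.quantile(treg, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = (treg > edges[b]) & (treg <= edges[b + 1])
        m = int(mask.sum())
        if m == 0:
            continue
        k_hi, k_lo = hi[mask].sum(), lo[mask].sum()
        odds_hi = (k_hi + 0.5) / (m - k_hi + 0.5)
        odds_lo = (k_lo + 0.5) / (m - k_lo + 0.5)
        out[b] = math.log(odds_hi) - math.log(odds_lo)
    return out


def delta_trend(deltas: np.ndarray) -> tuple[float, float]:
    """Spearman correlation (rho, p) of per-bin delta against bin index."""
    ok = np.isfinite(deltas)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(np.arange(len(deltas))[ok], deltas[ok])
    return float(rho), float(p)
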