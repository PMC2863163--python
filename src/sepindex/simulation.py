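"""Monte-Carlo machinery for the index-comparison study.

Survival times are drawn by inverse-transform sampling from

* proportional hazards:  ``S(t; z) = exp(-t e^{beta z})``  (unit exponential
  baseline, hazard ratio ``e^beta``), or
* proportional odds:     ``S(t; z) = (1 + t e^{beta z})^{-1}``  (standard
  log-logistic baseline; the covariate effect on the hazard wanes with time).

The covariate is Bernoulli(1/2) or Uniform[0, sqrt(3)]; both have variance 1/4
so effect sizes are comparable across the two laws.  Censoring is independent
of T given Z, either Uniform(0, r) or Exponential(rate gamma), with the
parameter solved so the expected overall censored fraction equals ``p_c``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, special

from .comparison import comparison_indices_many
from .risk_sets import SurvivalDataset, decompose_risk_sets
from .separability import index_stats_many

__all__ = [
    "SimulationConfig",
    "draw_covariate",
    "draw_survival",
    "solve_censoring_parameter",
    "simulate_dataset",
    "run_index_study",
    "NO_CENSORING",
]

NO_CENSORING = float("inf")  # sentinel returned by the solver when p_c = 0

UNIFORM_UPPER = np.sqrt(3.0)  # Uniform[0, a] with a^2/12 = 1/4

_MODELS = ("proportional_hazards", "proportional_odds")
_COVARIATES = ("bernoulli_half", "uniform_matched")
_MECHANISMS = ("none", "uniform", "exponential")


@dataclass
class SimulationConfig:
    """One cell of the simulation grid."""

    model: str = "proportional_hazards"
    effect: float = 1.0            # e^beta (hazard/odds ratio)
    covariate: str = "bernoulli_half"
    n: int = 100
    censoring: str = "none"        # "none" | "uniform" | "exponential"
    p_c: float = 0.0               # expected censored fraction
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.covariate not in _COVARIATES:
            raise ValueError(f"unknown covariate law {self.covariate!r}")
        if self.censoring not in _MECHANISMS:
            raise ValueError(f"unknown censoring mechanism {self.censoring!r}")
        if not (0.0 <= self.p_c < 1.0):
            raise ValueError("p_c must be in [0, 1)")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.censoring == "none" and self.p_c > 0:
            raise ValueError("p_c > 0 requires a censoring mechanism")

    @property
    def beta(self) -> float:
        return float(np.log(self.effect))


def draw_covariate(kind: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n covariate values; both laws have variance 1/4."""
    if kind == "bernoulli_half":
        return (rng.random(n) < 0.5).astype(float)
    if kind == "uniform_matched":
        return rng.random(n) * UNIFORM_UPPER
    raise ValueError(f"unknown covariate law {kind!r}")


def draw_survival(
    model: str, beta: float, z: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-transform survival times given covariates."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    z = np.asarray(z, dtype=float)
    u = rng.random(z.shape[0])
    scale = np.exp(-beta * z)
    if model == "proportional_hazards":
        return -np.log(u) * scale
    if model == "proportional_odds":
        return (1.0 / u - 1.0) * scale
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Censoring calibration
# ---------------------------------------------------------------------------

def _censored_prob_given_z(mechanism: str, param: float, model: str, lam: float) -> float:
    """P(C < T | Z) for hazard multiplier lam = e^{beta z}, closed forms."""
    if mechanism == "uniform":
        r = param
        # P(cens | z) = E[min(T, r)] / r = (1/r) * int_0^r S(t; z) dt
        if model == "proportional_hazards":
            return float(-np.expm1(-lam * r) / (lam * r))
        return float(np.log1p(lam * r) / (lam * r))
    if mechanism == "exponential":
        g = param
        if model == "proportional_hazards":
            return float(g / (g + lam))
        # int_0^inf g e^{-g t} / (1 + lam t) dt = (g/lam) e^{g/lam} E1(g/lam)
        x = g / lam
        return float(x * np.exp(x) * special.exp1(x)) if x < 500 else float(1 - 1 / x)
    raise ValueError(f"unknown censoring mechanism {mechanism!r}")


def _marginal_censored_prob(
    mechanism: str, param: float, model: str, beta: float, covariate: str
) -> float:
    """Expected censored fraction marginalized over the covariate law."""
    if covariate == "bernoulli_half":
        lams = np.array([1.0, np.exp(beta)])
        wts = np.array([0.5, 0.5])
    elif covariate == "uniform_matched":
        nodes, weights = np.polynomial.legendre.leggauss(64)
        zvals = (nodes + 1.0) / 2.0 * UNIFORM_UPPER
        lams = np.exp(beta * zvals)
        wts = weights / weights.sum()
    else:
        raise ValueError(f"unknown covariate law {covariate!r}")
    probs = [_censored_prob_given_z(mechanism, param, model, lam) for lam in lams]
    return float(np.dot(wts, probs))


def solve_censoring_parameter(
    mechanism: str, p_c: float, model: str, beta: float, covariate: str
) -> float:
    """Censoring parameter (uniform upper bound r, or exponential rate gamma)
    giving expected overall censored fraction ``p_c``.

    Returns the ``NO_CENSORING`` sentinel for ``p_c = 0``.
    """
    if p_c == 0.0 or mechanism == "none":
        return NO_CENSORING
    if not (0.0 < p_c < 1.0):
        raise ValueError("p_c must be in (0, 1)")

    def objective(param: float) -> float:
        return _marginal_censored_prob(mechanism, param, model, beta, covariate) - p_c

    # uniform: P(cens) decreases in r from 1 to 0; exponential: increases in
    # gamma from 0 to 1.  Bracket by doubling.
    lo, hi = 1e-9, 1.0
    f = objective
    for _ in range(200):
        if f(lo) * f(hi) <= 0:
            break
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("no censoring parameter in bounds")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    censoring_param: float | None = None,
) -> SurvivalDataset:
    """One replicate: covariate, survival and censoring times, follow-up data.

    ``censoring_param`` may be supplied to avoid re-solving inside replicate
    loops; it is solved from the config otherwise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z = draw_covariate(config.covariate, config.n, rng)
    t = draw_survival(config.model, config.beta, z, rng)
    if config.p_c == 0.0 or config.censoring == "none":
        x, event = t, np.ones(config.n, dtype=np.int8)
    else:
        if censoring_param is None:
            censoring_param = solve_censoring_parameter(
                config.censoring, config.p_c, config.model, config.beta, config.covariate
            )
        if config.censoring == "uniform":
            c = rng.random(config.n) * censoring_param
        else:
            c = rng.exponential(1.0 / censoring_param, config.n)
        x = np.minimum(t, c)
        event = (t <= c).astype(np.int8)
    return SurvivalDataset(time=x, event=event, covariates=z[None, :],
                           gene_ids=["Z"])


# ---------------------------------------------------------------------------
# Study runner
# ---------------------------------------------------------------------------

_INDEX_NAMES = ("separability", "allison", "allison_modified", "nagelkerke",
                "xu_oquigley")


def replicate_indices(
    config: SimulationConfig,
    rng: np.random.Generator,
    with_comparisons: bool = True,
    censoring_param: float | None = None,
) -> dict[str, float]:
    """All five indices on one simulated replicate (paired comparison)."""
    ds = simulate_dataset(config, rng, censoring_param=censoring_param)
    decomp = decompose_risk_sets(ds.time, ds.event)
    z = ds.covariates
    out = {"separability": float(index_stats_many(decomp, z)["index"][0])}
    if with_comparisons:
        comp = comparison_indices_many(decomp, z)
        for name in _INDEX_NAMES[1:]:
            out[name] = float(comp[name][0])
    return out


def run_index_study(
    configs: Iterable[SimulationConfig],
    with_comparisons: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Replicated simulation study over a grid of configurations.

    For each configuration: the mean and standard error of every index across
    replicates, plus the paired differences delta = separability - competitor
    with 95% confidence intervals.  All indices are computed on the same
    replicate datasets.
    """
    rows = []
    for config in configs:
        if config.replicates < 2:
            raise ValueError("at least 2 replicates required")
        rng = np.random.default_rng(config.seed)
        cpar = solve_censoring_parameter(
            config.censoring, config.p_c, config.model, config.beta, config.covariate
        )
        reps = {name: [] for name in _INDEX_NAMES}
        for _ in range(config.replicates):
            vals = replicate_indices(config, rng, with_comparisons, cpar)
            for name, v in vals.items():
                reps[name].append(v)
        base = {
            "model": config.model,
            "effect": config.effect,
            "covariate": config.covariate,
            "n": config.n,
            "censoring": config.censoring,
            "p_c": config.p_c,
            "replicates": config.replicates,
        }
        sep = np.asarray(reps["separability"])
        names = _INDEX_NAMES if with_comparisons else _INDEX_NAMES[:1]
        for name in names:
            vals = np.asarray(reps[name])
            m = np.nanmean(vals)
            se = np.nanstd(vals, ddof=1) / np.sqrt(np.sum(np.isfinite(vals)))
            row = dict(base, index_name=name, mean=m, se=se)
            if name != "separability":
                diff = sep - vals
                dm = np.nanmean(diff)
                dse = np.nanstd(diff, ddof=1) / np.sqrt(np.sum(np.isfinite(diff)))
                row.update(
                    delta_mean=dm,
                    delta_ci_low=dm - 1.96 * dse,
                    delta_ci_high=dm + 1.96 * dse,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def grid(
    models: Iterable[str] = ("proportional_hazards",),
    effects: Iterable[float] = (1.0, 1.25, 1.5, 1.75, 2.0, 3.0, 4.0, 5.0),
    covariates: Iterable[str] = ("bernoulli_half",),
    ns: Iterable[int] = (100,),
    censorings: Iterable[tuple[str, float]] = (("none", 0.0),),
    replicates: int = 1000,
    seed: int = 0,
) -> list[SimulationConfig]:
    """Cartesian simulation grid with per-cell derived seeds."""
    configs = []
    for i, (m, eff, cov, n, (mech, pc)) in enumerate(
        product(models, effects, covariates, ns, censorings)
    ):
        configs.append(
            SimulationConfig(
                model=m, effect=eff, covariate=cov, n=n,
                censoring=mech, p_c=pc, replicates=replicates,
                seed=(seed * 100003 + i) % (2**31 - 1),
            )
        )
    return configs
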