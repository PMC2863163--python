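"""Two-study synthetic gene-expression example for meta-selection benchmarks.

Each study has n subjects split into a low-risk half (xi = 0) and a high-risk
half (e^xi in {3, 5}); survival is exponential (proportional hazards) or
log-logistic (proportional odds), with uniform censoring calibrated so the
expected censored fraction is 30%.  The 1,000-gene matrix contains:

* genes 1-50:    LogNormal(4, 1.5) in the low-risk group vs LogNormal(0, 1.5)
* genes 51-100:  LogNormal(3, 1.5) vs LogNormal(0, 1.5)       (truly prognostic)
* genes 101-150: LogNormal(1, 1.5) for a random 40% of subjects
* genes 151-250: LogNormal(0.5, 1.5) for a random 50%
* genes 251-350: LogNormal(0.1, 1.5) for a random 70%   (structured, unlinked
  to risk status: distributional heterogeneity without prognostic content)
* genes 351-1000: LogNormal(0, 1.5) pure noise.

"Clumpy" dependence is added per 10-gene block: a shared LogNormal(0, 1)
subject vector, scaled by rho, is added to every gene of the block, giving
within-block correlation and independence across blocks.  Each study is then
quantile-normalized, as routinely done with real expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .risk_sets import SurvivalDataset
from .simulation import draw_survival, solve_censoring_parameter

__all__ = ["GenomicStudyConfig", "generate_meta_example", "quantile_normalize"]

N_GENES = 1000
N_PROGNOSTIC = 100
BLOCK_SIZE = 10

# (first gene, last gene inclusive, log-mean, fraction of subjects affected)
_STRUCTURED_BLOCKS = (
    (100, 150, 1.0, 0.40),
    (150, 250, 0.5, 0.50),
    (250, 350, 0.1, 0.70),
)
_SIGMA = 1.5


@dataclass
class GenomicStudyConfig:
    """One synthetic study of the two-study meta-selection example."""

    n: int = 150
    model: str = "proportional_hazards"   # or "proportional_odds"
    effect: float = 3.0                   # e^xi of the high-risk half
    p_c: float = 0.30                     # expected censored fraction (uniform C)
    rho: float = 0.5                      # clumpy-dependence strength
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n % 2:
            raise ValueError("n must be even (half low-risk, half high-risk)")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if not (0.0 <= self.rho):
            raise ValueError("rho must be nonnegative")


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Classical quantile normalization of a genes x samples matrix.

    Every column is forced onto the common reference distribution obtained by
    averaging the sorted columns; ties within a column receive the mean of the
    tied reference quantiles.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values are not supported")
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(X.shape[0])
    for c in range(X.shape[1]):
        ranks[order[:, c], c] = rows
    reference = np.sort(X, axis=0).mean(axis=1)
    out = reference[ranks]
    # average reference values over ties within each column
    for c in range(X.shape[1]):
        col = X[:, c]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if uniq.shape[0] == col.shape[0]:
            continue
        sums = np.bincount(inv, weights=out[:, c])
        out[:, c] = (sums / counts)[inv]
    return out


def _risk_groups(n: int) -> np.ndarray:
    """0 for the low-risk first half, 1 for the high-risk second half."""
    g = np.zeros(n, dtype=int)
    g[n // 2:] = 1
    return g


def _expression_matrix(config: GenomicStudyConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n
    high = _risk_groups(n).astype(bool)
    mu = np.zeros((N_GENES, n))
    mu[0:50, ~high] = 4.0
    mu[50:100, ~high] = 3.0
    for lo, hi, m, frac in _STRUCTURED_BLOCKS:
        affected = rng.random(n) < frac
        mu[lo:hi, affected] = m
    Z = rng.lognormal(mean=mu, sigma=_SIGMA)
    if config.rho > 0:
        for b in range(N_GENES // BLOCK_SIZE):
            shared = rng.lognormal(mean=0.0, sigma=1.0, size=n)
            Z[b * BLOCK_SIZE:(b + 1) * BLOCK_SIZE] += config.rho * shared
    return quantile_normalize(Z)


def _survival(config: GenomicStudyConfig, rng: np.random.Generator):
    n = config.n
    xi = np.log(config.effect) * _risk_groups(n)
    # risk group is a fair two-point covariate, so the Bernoulli(1/2) marginal
    # calibration applies to the expected censored fraction
    t = draw_survival(config.model, 1.0, xi, rng)  # scale exp(-xi): beta=1, z=xi
    r = solve_censoring_parameter(
        "uniform", config.p_c, config.model, np.log(config.effect), "bernoulli_half"
    )
    c = rng.random(n) * r
    x = np.minimum(t, c)
    event = (t <= c).astype(np.int8)
    return x, event


def generate_study(config: GenomicStudyConfig) -> SurvivalDataset:
    """One synthetic study: expression matrix + survival table."""
    rng = np.random.default_rng(config.seed)
    time, event = _survival(config, rng)
    expr = _expression_matrix(config, rng)
    return SurvivalDataset(
        time=time,
        event=event,
        covariates=expr,
        subject_ids=[f"s{i}" for i in range(config.n)],
        gene_ids=[f"g{i + 1}" for i in range(N_GENES)],
    )


def generate_meta_example(
    effect: float = 3.0,
    model: str = "proportional_hazards",
    rho: float = 0.5,
    seed: int = 0,
    n_a: int = 150,
    n_b: int = 50,
) -> tuple[SurvivalDataset, SurvivalDataset, np.ndarray]:
    """The two-study example (n = 150 and 50, shared gene universe).

    Returns ``(study_A, study_B, truth)`` where ``truth`` is the boolean mask
    of the 100 truly prognostic genes.
    """
    study_a = generate_study(GenomicStudyConfig(
        n=n_a, model=model, effect=effect, rho=rho, seed=seed * 2 + 1))
    study_b = generate_study(GenomicStudyConfig(
        n=n_b, model=model, effect=effect, rho=rho, seed=seed * 2 + 2))
    truth = np.zeros(N_GENES, dtype=bool)
    truth[:N_PROGNOSTIC] = True
    return study_a, study_b, truth
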