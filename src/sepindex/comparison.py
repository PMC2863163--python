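"""Likelihood-based predictive-accuracy indices used as comparators.

Four classical explained-variation indices for the one-covariate Cox model,
all evaluated at the partial-likelihood MLE:

* Allison:            ``1 - exp(-LR / n)``
* modified Allison:   ``1 - exp(-LR / k)`` with k the total number of failures
  (less sensitive to censoring than the original)
* Nagelkerke:         Allison divided by its maximum ``1 - exp(2 l(0) / n)``
* Xu--O'Quigley:      ``1 - exp(-2 Gamma)`` where Gamma is a Kaplan--Meier-
  weighted Kullback--Leibler divergence between the fitted and null
  conditional failure-selection probabilities on each risk set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .risk_sets import CoxFit, RiskSetDecomposition, fit_cox_many

__all__ = [
    "ComparisonIndices",
    "likelihood_ratio_indices",
    "xu_oquigley_index",
    "comparison_indices_many",
]


@dataclass
class ComparisonIndices:
    allison: float
    allison_modified: float
    nagelkerke: float
    xu_oquigley: float


def likelihood_ratio_indices(fit: CoxFit) -> tuple[float, float, float]:
    """(Allison, modified Allison, Nagelkerke) from a converged Cox fit.

    Non-converged fits yield NaNs (the indices are flagged missing rather than
    reported at a capped beta).
    """
    if not fit.converged:
        return (np.nan, np.nan, np.nan)
    lr = fit.lr_statistic
    allison = 1.0 - np.exp(-lr / fit.n)
    allison_mod = 1.0 - np.exp(-lr / fit.n_failures)
    r2_max = 1.0 - np.exp(2.0 * fit.loglik_null / fit.n)
    return (float(allison), float(allison_mod), float(allison / r2_max))


def _km_failure_weights(decomp: RiskSetDecomposition) -> np.ndarray:
    """Kaplan--Meier jumps of the distribution function of T at failure times.

    Renormalized to sum to one over the observed failure times (the last
    observation may be censored, in which case the raw jumps sum to < 1).
    Shape (k,), aligned with ``decomp.failure_time_indices``.
    """
    surv = np.cumprod(1.0 - decomp.d / decomp.n_at_risk)
    prev = np.concatenate(([1.0], surv[:-1]))
    jumps = (prev - surv)[decomp.failure_time_indices]
    total = jumps.sum()
    if total <= 0:
        raise ValueError("no Kaplan-Meier mass at failure times")
    return jumps / total


def xu_oquigley_index(
    decomp: RiskSetDecomposition, z: np.ndarray, fit: CoxFit
) -> float:
    """Xu--O'Quigley information-gain index for one covariate vector."""
    if not fit.converged:
        return np.nan
    return float(_xu_oquigley_many(decomp, np.asarray(z, float)[None, :],
                                   np.array([fit.beta_hat]))[0])


def _xu_oquigley_many(
    decomp: RiskSetDecomposition, Z: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Vectorized Gamma -> 1 - exp(-2 Gamma) across gene rows.

    ``pi_i(beta, t_j) = exp(beta z_i) / sum_{l in R_j} exp(beta z_l)``;
    ``Gamma = sum_j w_j sum_{i in R_j} pi_i(beta) log[pi_i(beta)/pi_i(0)]``
    with Kaplan--Meier jump weights ``w_j``.  The null probabilities are
    uniform on the risk set, so the inner sum is ``KL(pi || uniform)``.
    """
    Z = np.atleast_2d(Z)
    zs = Z[:, decomp.order]
    w = _km_failure_weights(decomp)
    gamma = np.zeros(Z.shape[0])
    for w_j, j in zip(w, decomp.failure_time_indices):
        s = decomp.start[j]
        a = beta[:, None] * zs[:, s:]
        a = a - a.max(axis=1, keepdims=True)
        ea = np.exp(a)
        pi = ea / ea.sum(axis=1, keepdims=True)
        n_j = decomp.n_at_risk[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            kl = np.sum(np.where(pi > 0, pi * np.log(pi * n_j), 0.0), axis=1)
        gamma += w_j * kl
    return 1.0 - np.exp(-2.0 * gamma)


def comparison_indices_many(
    decomp: RiskSetDecomposition, Z: np.ndarray, fits: list[CoxFit] | None = None
) -> dict[str, np.ndarray]:
    """All four comparison indices for every gene row of ``Z``.

    Returns arrays ``allison, allison_modified, nagelkerke, xu_oquigley,
    beta_hat, lr_statistic`` (NaN where the fit did not converge).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if fits is None:
        fits = fit_cox_many(decomp, Z)
    G = Z.shape[0]
    out = {
        name: np.full(G, np.nan)
        for name in ("allison", "allison_modified", "nagelkerke",
                     "xu_oquigley", "beta_hat", "lr_statistic")
    }
    conv = np.array([f.converged for f in fits])
    for g, fit in enumerate(fits):
        out["beta_hat"][g] = fit.beta_hat
        out["lr_statistic"][g] = fit.lr_statistic
        a, am, ng = likelihood_ratio_indices(fit)
        out["allison"][g] = a
        out["allison_modified"][g] = am
        out["nagelkerke"][g] = ng
    if conv.any():
        beta = np.array([fits[g].beta_hat for g in np.flatnonzero(conv)])
        out["xu_oquigley"][conv] = _xu_oquigley_many(decomp, Z[conv], beta)
    return out
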