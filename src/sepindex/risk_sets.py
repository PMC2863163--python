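"""Survival data containers, risk-set decomposition and the Breslow partial likelihood.

Everything downstream (the separability index, the likelihood-based comparison
indices, per-gene screening) is driven by a single combinatorial object: the
decomposition of the observed follow-up times into distinct times with their
death sets ``D(t_j)``, risk sets ``R(t_j)`` and leaving sets ``E(t_j)``.  Ties
among failures are handled with the Peto--Breslow approximation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SurvivalDataset",
    "RiskSetDecomposition",
    "CoxFit",
    "decompose_risk_sets",
    "breslow_log_partial_likelihood",
    "breslow_score",
    "fit_cox",
    "fit_cox_many",
]

# Newton solver settings (one-covariate Cox model, Breslow ties).
NEWTON_TOL = 1e-8          # |score| convergence tolerance, standardized covariate scale
NEWTON_MAX_ITER = 50
NEWTON_MAX_HALVINGS = 30
BETA_CAP = 20.0            # |beta| bound, standardized scale (monotone likelihoods)
_ETA_CLIP = 500.0          # clip on beta*z before exponentiation


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SurvivalDataset:
    """One study: follow-up times, event indicators and a genes x samples matrix.

    Parameters
    ----------
    time : array of shape (n,)
        Observed follow-up ``min(T_i, C_i)``; nonnegative.
    event : array of shape (n,)
        1 if the follow-up ended with the event of interest, 0 if censored.
    covariates : array of shape (G, n)
        One row per gene (covariate), one column per subject.
    subject_ids, gene_ids : sequences of labels, optional.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[None, :]
        self.covariates = cov
        n = self.time.shape[0]
        if self.event.shape[0] != n:
            raise ValueError("time and event must have the same length")
        if np.any(self.time < 0):
            raise ValueError("negative follow-up time")
        ev = np.asarray(self.event, dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValueError("event indicator must be 0/1")
        self.event = ev.astype(np.int8)
        if self.covariates.shape[1] != n:
            raise ValueError(
                f"covariate matrix has {self.covariates.shape[1]} columns "
                f"for {n} subjects"
            )
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(self.covariates.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.time.shape[0]

    @property
    def n_genes(self) -> int:
        return self.covariates.shape[0]

    def gene(self, gene_id: str) -> np.ndarray:
        """Covariate vector for one gene id."""
        try:
            row = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None
        return self.covariates[row]

    def decompose(self) -> "RiskSetDecomposition":
        return decompose_risk_sets(self.time, self.event)


@dataclass
class RiskSetDecomposition:
    """Distinct observed times with death/risk/leaving sets and counts.

    Subjects are stored once, sorted by follow-up time (stable sort).  The risk
    set at distinct time ``t_j`` is the suffix ``order[start[j]:]`` of that
    ordering; the leaving set ``E(t_j)`` is the slice ``order[start[j]:start[j+1]]``.
    ``d``, ``n_at_risk`` and ``e`` are the cardinals ``d_j``, ``n_j``, ``e_j``.
    """

    distinct_times: np.ndarray     # (N,) strictly increasing
    order: np.ndarray              # (n,) subject indices sorted by time
    start: np.ndarray              # (N+1,) slice bounds into `order` per distinct time
    subject_time_index: np.ndarray # (n,) distinct-time index of each subject
    d: np.ndarray                  # (N,) failures at t_j
    n_at_risk: np.ndarray          # (N,) at risk at t_j
    e: np.ndarray                  # (N,) failing or censored at t_j
    event_sorted: np.ndarray       # (n,) event indicator in `order` ordering

    @property
    def n_distinct(self) -> int:
        """N, the number of distinct observed times."""
        return self.distinct_times.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.order.shape[0]

    @property
    def k_failure_times(self) -> int:
        """k, the number of distinct failure times (d_j >= 1)."""
        return int(np.count_nonzero(self.d))

    @property
    def n_failures(self) -> int:
        """Total number of failures, ties included."""
        return int(self.d.sum())

    @property
    def death_indicator(self) -> np.ndarray:
        """1 if at least one death at t_j, else 0."""
        return (self.d > 0).astype(np.int8)

    @property
    def failure_time_indices(self) -> np.ndarray:
        """Indices j with d_j >= 1."""
        return np.flatnonzero(self.d > 0)

    # -- explicit sets (small-n conveniences; the array form above is what the
    #    numeric code uses) ----------------------------------------------------

    def R(self, j: int) -> np.ndarray:
        """Risk set at t_j: subjects with follow-up >= t_j."""
        return np.sort(self.order[self.start[j]:])

    def D(self, j: int) -> np.ndarray:
        """Subjects failing at t_j."""
        block = self.order[self.start[j]:self.start[j + 1]]
        return np.sort(block[self.event_sorted[self.start[j]:self.start[j + 1]] == 1])

    def E(self, j: int) -> np.ndarray:
        """Subjects failing or censored at t_j."""
        return np.sort(self.order[self.start[j]:self.start[j + 1]])

    def Rstar(self, j: int) -> np.ndarray:
        """R(t_j) without the subjects failing at t_j."""
        return np.sort(np.setdiff1d(self.R(j), self.D(j), assume_unique=True))

    def rstar_pair(self, l: int, j: int) -> np.ndarray:
        """R*(t_l(-j)): risk set at t_l < t_j without the subjects leaving at t_j."""
        if not l < j:
            raise ValueError("rstar_pair requires t_l < t_j (l < j)")
        return np.sort(np.setdiff1d(self.R(l), self.E(j), assume_unique=True))


@dataclass
class CoxFit:
    """One-covariate Cox fit on the Breslow partial likelihood."""

    beta_hat: float
    loglik_null: float
    loglik_hat: float
    lr_statistic: float
    n: int
    k_events: int      # distinct failure times
    n_failures: int    # total failures (ties included)
    converged: bool


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def decompose_risk_sets(time: Sequence[float], event: Sequence[int]) -> RiskSetDecomposition:
    """Decompose follow-up data into distinct times with D/R/E sets and counts.

    Purely combinatorial and deterministic.  Censored subjects tied with
    failures at the same time remain in the risk set at that time (censoring
    is taken to happen just after failure).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if np.any(time < 0):
        raise ValueError("negative follow-up time")
    ev = np.asarray(event, dtype=float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValueError("event indicator must be 0/1")
    event = ev.astype(np.int8)
    if event.sum() == 0:
        raise ValueError("no failures: at least one event is required")

    order = np.argsort(time, kind="stable")
    ts = time[order]
    es = event[order]
    n = ts.shape[0]

    new_time = np.empty(n, dtype=bool)
    new_time[0] = True
    new_time[1:] = ts[1:] > ts[:-1]
    start_idx = np.flatnonzero(new_time)
    distinct_times = ts[start_idx]
    start = np.append(start_idx, n)

    subject_time_index = np.empty(n, dtype=np.int64)
    subject_time_index[order] = np.cumsum(new_time) - 1

    e = np.diff(start)
    n_at_risk = n - start[:-1]
    d = np.add.reduceat(es.astype(np.int64), start[:-1])

    return RiskSetDecomposition(
        distinct_times=distinct_times,
        order=order,
        start=start,
        subject_time_index=subject_time_index,
        d=d,
        n_at_risk=n_at_risk,
        e=e,
        event_sorted=es,
    )


# ---------------------------------------------------------------------------
# Breslow partial likelihood and score
# ---------------------------------------------------------------------------

def _sorted_covariate(decomp: RiskSetDecomposition, z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != decomp.n_subjects:
        raise ValueError("covariate vector length does not match subject count")
    return z[..., decomp.order]


def _suffix_logsumexp(a: np.ndarray) -> np.ndarray:
    """log(sum(exp(a[i:]))) for every i, along the last axis, numerically stable."""
    rev = a[..., ::-1]
    return np.logaddexp.accumulate(rev, axis=-1)[..., ::-1]


def breslow_log_partial_likelihood(
    decomp: RiskSetDecomposition, z: np.ndarray, beta: float
) -> float:
    """Breslow-approximated Cox partial log-likelihood at ``beta``.

    ``l(beta) = sum_j [ beta * sum_{i in D_j} z_i - d_j * log sum_{i in R_j} exp(beta z_i) ]``
    over distinct times (terms with d_j = 0 vanish).
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    zs = _sorted_covariate(decomp, z)
    eta = np.clip(beta * zs, -_ETA_CLIP, _ETA_CLIP)
    log_risk = _suffix_logsumexp(eta)[decomp.start[:-1]]
    death_cov = np.add.reduceat(zs * decomp.event_sorted, decomp.start[:-1])
    return float(np.sum(beta * death_cov - decomp.d * log_risk))


def breslow_score(decomp: RiskSetDecomposition, z: np.ndarray, beta: float) -> float:
    """First derivative of the Breslow partial log-likelihood at ``beta``.

    ``U(beta) = sum_j [ sum_{i in D_j} z_i - d_j * weighted-mean_{R_j}(z) ]``
    with weights proportional to ``exp(beta z)`` on the risk set.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    zs = _sorted_covariate(decomp, z)
    eta = np.clip(beta * zs, -_ETA_CLIP, _ETA_CLIP)
    m = _suffix_logsumexp(eta)
    w = np.exp(eta - m[..., 0])  # shift by global max suffix for stability
    s0 = np.cumsum(w[::-1])[::-1][decomp.start[:-1]]
    s1 = np.cumsum((w * zs)[::-1])[::-1][decomp.start[:-1]]
    death_cov = np.add.reduceat(zs * decomp.event_sorted, decomp.start[:-1])
    return float(np.sum(death_cov - decomp.d * s1 / s0))


# ---------------------------------------------------------------------------
# Newton-Raphson fit (scalar wrapper around the vectorized many-gene solver)
# ---------------------------------------------------------------------------

def _loglik_score_info_many(
    decomp: RiskSetDecomposition, zs: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(loglik, score, information) per gene; ``zs`` is (G, n) in sorted order."""
    eta = np.clip(beta[:, None] * zs, -_ETA_CLIP, _ETA_CLIP)
    emax = np.max(eta, axis=1, keepdims=True)
    w = np.exp(eta - emax)
    cols = decomp.start[:-1]
    s0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1][:, cols]
    s1 = np.cumsum((w * zs)[:, ::-1], axis=1)[:, ::-1][:, cols]
    s2 = np.cumsum((w * zs * zs)[:, ::-1], axis=1)[:, ::-1][:, cols]
    death_cov = np.add.reduceat(zs * decomp.event_sorted, cols, axis=1)
    d = decomp.d
    loglik = np.sum(beta[:, None] * death_cov - d * (np.log(s0) + emax), axis=1)
    mean = s1 / s0
    score = np.sum(death_cov - d * mean, axis=1)
    info = np.sum(d * (s2 / s0 - mean * mean), axis=1)
    return loglik, score, info


def fit_cox_many(decomp: RiskSetDecomposition, Z: np.ndarray) -> list[CoxFit]:
    """Newton--Raphson Breslow--Cox fits for every row of ``Z`` (G, n).

    The covariate is standardized internally (centered, unit variance); beta is
    reported on the original scale.  Step-halving on likelihood decrease; betas
    capped at +/-20 on the standardized scale and flagged non-converged when a
    monotone likelihood pushes them to the cap.  Constant covariates yield a
    NaN, non-converged fit.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    zs_raw = Z[:, decomp.order]
    sd = zs_raw.std(axis=1)
    ok = sd > 0
    sd_safe = np.where(ok, sd, 1.0)
    zs = (zs_raw - zs_raw.mean(axis=1, keepdims=True)) / sd_safe[:, None]

    G = zs.shape[0]
    beta = np.zeros(G)
    ll0, score0, _ = _loglik_score_info_many(decomp, zs, beta)
    ll = ll0.copy()
    converged = np.zeros(G, dtype=bool)
    active = ok.copy()

    for _ in range(NEWTON_MAX_ITER):
        if not active.any():
            break
        _, score, info = _loglik_score_info_many(decomp, zs[active], beta[active])
        done = np.abs(score) < NEWTON_TOL
        idx_active = np.flatnonzero(active)
        converged[idx_active[done]] = True
        active[idx_active[done]] = False
        if not active.any():
            break
        idx_active = np.flatnonzero(active)
        score = score[~done]
        info = info[~done]
        step = score / np.where(info > 0, info, 1.0)
        step = np.clip(step, -5.0, 5.0)
        beta_a = beta[idx_active]
        ll_a = ll[idx_active]
        zs_a = zs[idx_active]
        cand = np.clip(beta_a + step, -BETA_CAP, BETA_CAP)
        for _h in range(NEWTON_MAX_HALVINGS):
            ll_new, _, _ = _loglik_score_info_many(decomp, zs_a, cand)
            bad = ll_new < ll_a - 1e-12
            if not bad.any():
                break
            cand[bad] = (cand[bad] + beta_a[bad]) / 2.0
        beta[idx_active] = cand
        ll[idx_active], _, _ = _loglik_score_info_many(decomp, zs_a, cand)
        at_cap = np.abs(cand) >= BETA_CAP - 1e-9
        # capped betas: monotone likelihood, stop iterating, leave non-converged
        active[idx_active[at_cap]] = False

    lr = 2.0 * (ll - ll0)
    fits = []
    for g in range(G):
        if not ok[g]:
            fits.append(
                CoxFit(np.nan, np.nan, np.nan, np.nan, decomp.n_subjects,
                       decomp.k_failure_times, decomp.n_failures, False)
            )
            continue
        fits.append(
            CoxFit(
                beta_hat=float(beta[g] / sd[g]),
                loglik_null=float(ll0[g]),
                loglik_hat=float(ll[g]),
                lr_statistic=float(max(lr[g], 0.0)),
                n=decomp.n_subjects,
                k_events=decomp.k_failure_times,
                n_failures=decomp.n_failures,
                converged=bool(converged[g]),
            )
        )
    return fits


def fit_cox(decomp: RiskSetDecomposition, z: np.ndarray) -> CoxFit:
    """Fit the one-covariate Cox model by Newton--Raphson (Breslow ties).

    Raises ``ValueError`` for a constant covariate; a monotone likelihood is
    returned with beta at the cap and ``converged=False``.
    """
    z = np.asarray(z, dtype=float)
    if np.ptp(z) == 0:
        raise ValueError("constant covariate: Cox model is not identifiable")
    return fit_cox_many(decomp, z[None, :])[0]
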