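"""The separability index for censored time-to-event outcomes.

At each distinct time ``t_j`` the null-score component

    U_j = sum_{i in D_j} z_i - d_j * mean_{R_j}(z)

contrasts the covariates of the subjects failing at ``t_j`` with the risk set,
i.e. measures how well the covariate separates the event group from the
non-event group at that time.  The global statistic ``Delta0 = sum_j U_j`` is
the Cox score at beta = 0.

Because the ``U_j`` are not independent, the index is built instead on the
robust components ``W_j`` obtained by aggregating Lin--Wei score residuals by
distinct time: each subject carries the residual

    L_i = delta_i (z_i - zbar(t_{(i)})) - sum_{t_j <= X_i} (d_j/n_j)(z_i - zbar(t_j))

and ``W_j = sum_{i in E(t_j)} L_i``.  The ``W_j`` are asymptotically i.i.d.
and their sum equals ``sum_j U_j`` exactly.

By the Cauchy--Schwarz inequality over the N distinct-time components,
``Delta0^2 = (sum_j W_j)^2`` ranges from 0 to ``Dmax = N * sum_j W_j^2``, the
maximum being approached as the covariate effect grows without bound.  The
index

    I = Delta0^2 / Dmax = S0 / N,    S0 = (sum W_j)^2 / sum W_j^2

lies in [0, 1], approaches 0 under no association and grows with the hazard
ratio, and is ``1/N`` times the robust score statistic ``S0``, whose null
distribution is asymptotically chi-square with 1 degree of freedom.  Dividing
by ``N`` is what removes the sample-size dependence that makes raw test
statistics unsuitable for ranking genes across studies of different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .risk_sets import RiskSetDecomposition, SurvivalDataset

__all__ = [
    "IndexResult",
    "score_components_null",
    "robust_components_null",
    "delta_max",
    "separability_index",
    "index_table_arrays",
]


@dataclass
class IndexResult:
    """Separability index and robust score test for one gene."""

    gene_id: str
    delta0: float             # sum of robust components W_j (= Cox score at 0)
    delta_max: float          # N * sum W_j^2, the Cauchy-Schwarz maximum of delta0^2
    index: float              # delta0^2 / delta_max, in [0, 1]
    direction: str            # "HR>1" or "HR<1", from the sign of delta0
    robust_score_stat: float  # S0 = delta0^2 / sum W_j^2
    p_value: float            # chi-square(1) upper tail of S0
    q_value: float | None = None


def _means_on_risk_sets(decomp: RiskSetDecomposition, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sorted covariate (G,n), risk-set means (G,N)) for each gene row."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != decomp.n_subjects:
        raise ValueError("covariate length does not match subject count")
    zs = Z[:, decomp.order]
    suffix = np.cumsum(zs[:, ::-1], axis=1)[:, ::-1][:, decomp.start[:-1]]
    return zs, suffix / decomp.n_at_risk


def score_components_many(decomp: RiskSetDecomposition, Z: np.ndarray) -> np.ndarray:
    """Null-score components U_j for every gene row; shape (G, N)."""
    zs, zbar = _means_on_risk_sets(decomp, Z)
    death_cov = np.add.reduceat(zs * decomp.event_sorted, decomp.start[:-1], axis=1)
    return death_cov - decomp.d * zbar


def robust_components_many(decomp: RiskSetDecomposition, Z: np.ndarray) -> np.ndarray:
    """Robust components W_j (Lin--Wei residuals aggregated by distinct time).

    Shape (G, N).  ``W.sum(axis=1)`` equals ``U.sum(axis=1)`` exactly.
    """
    zs, zbar = _means_on_risk_sets(decomp, Z)
    h = decomp.d / decomp.n_at_risk                     # hazard increments, (N,)
    H = np.cumsum(h)                                    # cumulative hazard
    A = np.cumsum(h * zbar, axis=1)                     # cumulated hazard-weighted means
    jidx = decomp.subject_time_index[decomp.order]      # distinct-time index, sorted order
    resid = (
        decomp.event_sorted * (zs - zbar[:, jidx])
        - zs * H[jidx]
        + A[:, jidx]
    )
    return np.add.reduceat(resid, decomp.start[:-1], axis=1)


def score_components_null(decomp: RiskSetDecomposition, z: np.ndarray) -> np.ndarray:
    """U_j per distinct time for one covariate vector; shape (N,)."""
    return score_components_many(decomp, np.asarray(z, dtype=float)[None, :])[0]


def robust_components_null(decomp: RiskSetDecomposition, z: np.ndarray) -> np.ndarray:
    """W_j per distinct time for one covariate vector; shape (N,)."""
    return robust_components_many(decomp, np.asarray(z, dtype=float)[None, :])[0]


def delta_max(decomp: RiskSetDecomposition, z: np.ndarray) -> float:
    """Theoretical maximum of ``Delta0^2``: ``N * sum_j W_j^2``.

    This is the Cauchy--Schwarz bound on ``(sum_j W_j)^2`` over the N
    distinct-time robust components; it is approached as the covariate effect
    tends to infinity (all components then pull in one direction with
    comparable weight).
    """
    W = robust_components_null(decomp, z)
    ssq = float(np.sum(W * W))
    if ssq <= 0.0:
        raise ValueError("zero separability scale: covariate constant on risk sets")
    return decomp.n_distinct * ssq


def index_stats_many(
    decomp: RiskSetDecomposition, Z: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized index computation across gene rows.

    Returns arrays ``delta0, dmax, index, score_stat, p_value`` of shape (G,).
    Degenerate genes (covariate constant on risk sets) yield NaN.
    """
    W = robust_components_many(decomp, Z)
    delta0 = W.sum(axis=1)
    ssq = np.sum(W * W, axis=1)
    N = decomp.n_distinct
    with np.errstate(divide="ignore", invalid="ignore"):
        s0 = np.where(ssq > 0, delta0 * delta0 / ssq, np.nan)
    dmax = np.where(ssq > 0, N * ssq, np.nan)
    index = s0 / N
    p = stats.chi2.sf(s0, df=1)
    return {
        "delta0": delta0,
        "dmax": dmax,
        "index": index,
        "score_stat": s0,
        "p_value": p,
    }


def separability_index(dataset: SurvivalDataset, gene: str) -> IndexResult:
    """Separability index of one gene in a study.

    Raises ``ValueError`` when the gene's expression is constant on the risk
    sets (the index is undefined: zero separability scale).
    """
    z = dataset.gene(gene)
    decomp = dataset.decompose()
    res = index_stats_many(decomp, z[None, :])
    if not np.isfinite(res["index"][0]):
        raise ValueError(f"zero separability scale for gene {gene!r}")
    d0 = float(res["delta0"][0])
    return IndexResult(
        gene_id=gene,
        delta0=d0,
        delta_max=float(res["dmax"][0]),
        index=float(res["index"][0]),
        direction="HR>1" if d0 >= 0 else "HR<1",
        robust_score_stat=float(res["score_stat"][0]),
        p_value=float(res["p_value"][0]),
    )


def index_table_arrays(dataset: SurvivalDataset) -> dict[str, np.ndarray]:
    """Index statistics for every gene of a study, as plain arrays.

    Used by the screening/meta layers; see :func:`sepindex.meta.gene_table`
    for the user-facing DataFrame version.
    """
    decomp = dataset.decompose()
    return index_stats_many(decomp, dataset.covariates)
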