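"""Cross-study gene meta-selection.

Given per-study gene rankings by some criterion (the separability index, a
likelihood-based index, or an FDR q-value), genes passing the threshold in
every study form the intersection selection.  The threshold itself is chosen
with the intersection-ratio procedure: for each candidate threshold, compare
the observed number of genes selected in common, O(t), to the number expected
under independence of the studies, E(t) = G * prod_k (|S_k(t)| / G), and keep
thresholds whose ratio O/E exceeds 2 (genuine cross-study concordance).

Operating characteristics on synthetic data are summarized as the true
positive fraction (selected among truly prognostic genes) and true negative
fraction (unselected among non-prognostic genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .comparison import comparison_indices_many
from .risk_sets import SurvivalDataset, decompose_risk_sets
from .separability import index_stats_many
from .synthetic import generate_meta_example

__all__ = [
    "MetaSelectionResult",
    "gene_table",
    "select_common",
    "intersection_ratio_curve",
    "qvalues",
    "tpf_tnf",
    "run_meta_study",
]

RATIO_RULE = 2.0  # a threshold qualifies when observed/expected > 2

#: criteria where larger values are stronger evidence; q-values/p-values are
#: "smaller is stronger"
_DESCENDING = ("index", "allison", "allison_modified", "nagelkerke",
               "xu_oquigley", "score_stat", "lr_statistic")


@dataclass
class MetaSelectionResult:
    """Intersection-ratio curve and the resulting selection."""

    thresholds: np.ndarray            # criterion-scale thresholds (per grid point)
    top_fractions: np.ndarray         # grid of top fractions the thresholds came from
    observed: np.ndarray              # O(t): genes in common
    expected: np.ndarray              # E(t) under independence
    ratio: np.ndarray                 # O/E (NaN when E = 0)
    qualifying: np.ndarray            # boolean, ratio > 2
    chosen_threshold: float | None    # loosest qualifying threshold
    selected: list[str] = field(default_factory=list)
    per_study_values: pd.DataFrame | None = None


def gene_table(
    dataset: SurvivalDataset,
    with_comparisons: bool = False,
    with_qvalues: bool = False,
) -> pd.DataFrame:
    """Per-gene separability results for one study.

    Columns: gene, index, delta0, dmax, direction, score_stat, pvalue
    (plus qvalue, and the comparison indices / LR columns on request).
    """
    decomp = decompose_risk_sets(dataset.time, dataset.event)
    res = index_stats_many(decomp, dataset.covariates)
    table = pd.DataFrame(
        {
            "gene": dataset.gene_ids,
            "index": res["index"],
            "delta0": res["delta0"],
            "dmax": res["dmax"],
            "direction": np.where(res["delta0"] >= 0, "HR>1", "HR<1"),
            "score_stat": res["score_stat"],
            "pvalue": res["p_value"],
        }
    )
    if with_qvalues:
        table["qvalue"] = qvalues(table["pvalue"].to_numpy())
    if with_comparisons:
        comp = comparison_indices_many(decomp, dataset.covariates)
        for name in ("allison", "allison_modified", "nagelkerke", "xu_oquigley",
                     "beta_hat", "lr_statistic"):
            table[name] = comp[name]
        table["lr_pvalue"] = stats.chi2.sf(comp["lr_statistic"], df=1)
        if with_qvalues:
            table["lr_qvalue"] = qvalues(table["lr_pvalue"].to_numpy())
    return table


def _criterion_values(table: pd.DataFrame, criterion: str) -> pd.Series:
    if criterion not in table.columns:
        raise KeyError(f"criterion {criterion!r} not in study table")
    return table.set_index("gene")[criterion]


def _passes(values: pd.Series, criterion: str, threshold: float) -> pd.Series:
    if criterion in _DESCENDING:
        return values >= threshold
    return values <= threshold


def _common_universe(per_study: list[pd.DataFrame]) -> list[str]:
    universe = set(per_study[0]["gene"])
    for t in per_study[1:]:
        universe &= set(t["gene"])
    if not universe:
        raise ValueError("studies share no genes")
    return sorted(universe)


def select_common(
    per_study: list[pd.DataFrame], criterion: str, threshold: float
) -> pd.DataFrame:
    """Genes passing the criterion threshold in every study.

    Returns a frame with one row per selected gene, its per-study criterion
    values, and whether the effect direction is concordant across studies.
    """
    if len(per_study) < 2:
        raise ValueError("meta-selection needs at least two studies")
    universe = _common_universe(per_study)
    keep = pd.Series(True, index=universe)
    vals = {}
    dirs = []
    for s, table in enumerate(per_study):
        v = _criterion_values(table, criterion).reindex(universe)
        keep &= _passes(v, criterion, threshold).fillna(False)
        vals[f"study{s + 1}_{criterion}"] = v
        if "direction" in table.columns:
            dirs.append(table.set_index("gene")["direction"].reindex(universe))
    out = pd.DataFrame(vals).loc[keep[keep].index]
    if dirs:
        d = pd.concat(dirs, axis=1).loc[out.index]
        out["direction_concordant"] = (d.nunique(axis=1) == 1)
        out["direction"] = d.iloc[:, 0].where(out["direction_concordant"], "mixed")
    out.index.name = "gene"
    return out.reset_index()


def _default_top_fractions() -> np.ndarray:
    return np.linspace(0.005, 0.20, 40)


def intersection_ratio_curve(
    per_study: list[pd.DataFrame],
    criterion: str = "index",
    top_fractions: np.ndarray | None = None,
) -> MetaSelectionResult:
    """Observed/expected common-gene counts over a grid of thresholds.

    Thresholds are criterion quantiles (top fractions of the pooled per-study
    values) so that grids are comparable across studies; for each grid point
    the threshold applied is the loosest per-study value retaining that top
    fraction in every study.  The chosen threshold is the loosest one whose
    observed/expected ratio exceeds 2.
    """
    if top_fractions is None:
        top_fractions = _default_top_fractions()
    top_fractions = np.asarray(top_fractions, dtype=float)
    if top_fractions.size == 0:
        raise ValueError("empty threshold grid")
    universe = _common_universe(per_study)
    G = len(universe)
    values = [
        _criterion_values(t, criterion).reindex(universe) for t in per_study
    ]
    observed = np.zeros(top_fractions.size)
    expected = np.zeros(top_fractions.size)
    thresholds = np.zeros(top_fractions.size)
    descending = criterion in _DESCENDING
    for i, frac in enumerate(top_fractions):
        q = 1.0 - frac if descending else frac
        per_thr = [np.nanquantile(v.to_numpy(), q) for v in values]
        # loosest per-study threshold achieving the top fraction in all studies
        thr = min(per_thr) if descending else max(per_thr)
        thresholds[i] = thr
        sel = [set(v.index[_passes(v, criterion, thr).fillna(False)]) for v in values]
        inter = set.intersection(*sel)
        observed[i] = len(inter)
        expected[i] = G * np.prod([len(s) / G for s in sel])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.nan)
    qualifying = np.nan_to_num(ratio) > RATIO_RULE
    chosen = None
    selected: list[str] = []
    if qualifying.any():
        # loosest qualifying threshold = largest qualifying top fraction
        i_star = np.flatnonzero(qualifying)[np.argmax(top_fractions[qualifying])]
        chosen = float(thresholds[i_star])
        sel_frame = select_common(per_study, criterion, chosen)
        selected = sel_frame["gene"].tolist()
    return MetaSelectionResult(
        thresholds=thresholds,
        top_fractions=top_fractions,
        observed=observed,
        expected=expected,
        ratio=ratio,
        qualifying=qualifying,
        chosen_threshold=chosen,
        selected=selected,
    )


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey smoother estimate of the null proportion pi0.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` on a lambda grid,
    smoothed with a cubic spline and read off at the largest lambda; clamped
    to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    if np.all(pi0_l <= 0):
        return 1.0 / m
    spline = interpolate.UnivariateSpline(lambdas, pi0_l, k=3)
    pi0 = float(spline(lambdas[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey-type FDR q-values (monotone in p).

    With ``pi0=1`` this reduces exactly to Benjamini--Hochberg adjusted
    p-values; by default pi0 is estimated with the smoother.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if not finite.all():
        q = np.full(p.shape, np.nan)
        q[finite] = qvalues(p[finite], pi0=pi0)
        return q
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def tpf_tnf(selected: set[str] | list[str], truth: set[str] | list[str],
            universe: list[str]) -> tuple[float, float]:
    """True positive and true negative fractions of a selection.

    TPF = |selected & truth| / |truth|;
    TNF = |unselected & non-truth| / |non-truth|.
    """
    selected = set(selected)
    truth = set(truth)
    non_truth = set(universe) - truth
    tpf = len(selected & truth) / len(truth) if truth else np.nan
    tnf = len(non_truth - selected) / len(non_truth) if non_truth else np.nan
    return tpf, tnf


# ---------------------------------------------------------------------------
# Operating-characteristics study on the synthetic two-study example
# ---------------------------------------------------------------------------

_CRITERIA = ("index", "allison", "allison_modified", "nagelkerke", "xu_oquigley")


def run_meta_study(
    effect: float = 5.0,
    model: str = "proportional_hazards",
    rho: float = 0.5,
    iterations: int = 100,
    top_fractions: np.ndarray | None = None,
    seed: int = 0,
    log_expression: bool = True,
) -> pd.DataFrame:
    """Mean TPF/TNF of each criterion at matched top-fraction thresholds.

    Each iteration generates a fresh two-study example, ranks genes by every
    criterion in both studies, intersects the per-study top fractions, and
    scores the intersection against the 100 truly prognostic genes.  Rows:
    one per (criterion, top_fraction) with TPF/TNF averaged over iterations.

    The generator emits intensity-scale expression; per-gene survival
    screening follows the field convention of a log-linear effect, so the
    matrices are log-transformed before the indices are computed (disable
    with ``log_expression=False``).
    """
    if top_fractions is None:
        top_fractions = np.linspace(0.02, 0.20, 10)
    top_fractions = np.asarray(top_fractions, dtype=float)
    acc: dict[tuple[str, float], list[tuple[float, float]]] = {
        (c, f): [] for c in _CRITERIA for f in top_fractions
    }
    for it in range(iterations):
        study_a, study_b, truth_mask = generate_meta_example(
            effect=effect, model=model, rho=rho, seed=seed * 1009 + it
        )
        if log_expression:
            for s in (study_a, study_b):
                s.covariates = np.log(s.covariates)
        tables = [
            gene_table(s, with_comparisons=True) for s in (study_a, study_b)
        ]
        universe = tables[0]["gene"].tolist()
        truth = [g for g, t in zip(universe, truth_mask) if t]
        for criterion in _CRITERIA:
            vals = [t.set_index("gene")[criterion] for t in tables]
            for frac in top_fractions:
                sel_sets = []
                for v in vals:
                    arr = v.to_numpy()
                    thr = np.nanquantile(arr, 1.0 - frac)
                    sel_sets.append(set(v.index[np.nan_to_num(arr, nan=-np.inf) >= thr]))
                inter = set.intersection(*sel_sets)
                acc[(criterion, frac)].append(tpf_tnf(inter, truth, universe))
    rows = []
    for (criterion, frac), pairs in acc.items():
        arr = np.asarray(pairs)
        rows.append(
            {
                "criterion": criterion,
                "top_fraction": frac,
                "tpf": arr[:, 0].mean(),
                "tnf": arr[:, 1].mean(),
                "model": model,
                "effect": effect,
                "rho": rho,
                "iterations": iterations,
            }
        )
    return pd.DataFrame(rows)
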