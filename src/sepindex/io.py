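"""Readers and writers for study bundles and result tables.

Expression matrices are TSV/CSV with genes as rows (first column the gene id,
remaining columns samples); survival tables have columns ``sample``, ``time``,
``event`` (0/1).  Samples are reconciled by id, never by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .risk_sets import SurvivalDataset

__all__ = ["StudyBundle", "load_study", "write_results", "write_study"]

logger = logging.getLogger("sepindex")


@dataclass
class StudyBundle:
    """One loaded study plus the sample-reconciliation report."""

    path: str
    dataset: SurvivalDataset
    dropped_expr_samples: list[str] = field(default_factory=list)
    dropped_surv_samples: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def load_study(
    expr_path: str | Path, surv_path: str | Path, transpose: bool = False
) -> StudyBundle:
    """Load and reconcile an expression matrix with its survival table.

    Samples present in only one of the two files are dropped (and reported);
    genes with missing values are dropped per study.  Raises on zero sample
    overlap, duplicate sample ids, or non-binary event codes.
    """
    expr = _read_table(expr_path)
    surv = _read_table(surv_path)
    if transpose:
        expr = expr.set_index(expr.columns[0]).T.reset_index()
        expr = expr.rename(columns={"index": "gene"})
    gene_col = expr.columns[0]
    expr = expr.set_index(gene_col)
    expr.index = expr.index.astype(str)

    required = {"sample", "time", "event"}
    if not required.issubset(surv.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    surv["sample"] = surv["sample"].astype(str)
    if surv["sample"].duplicated().any():
        dups = surv.loc[surv["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in survival table: {dups}")
    expr.columns = expr.columns.astype(str)
    if expr.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")

    bad_events = surv.loc[~surv["event"].isin([0, 1, 0.0, 1.0]), "sample"].tolist()
    if bad_events:
        raise ValueError(f"non-binary event codes for samples: {bad_events}")

    expr_samples = list(expr.columns)
    surv_samples = list(surv["sample"])
    common = [s for s in surv_samples if s in set(expr_samples)]
    if not common:
        raise ValueError("expression and survival tables share no samples")
    dropped_expr = sorted(set(expr_samples) - set(common))
    dropped_surv = sorted(set(surv_samples) - set(common))
    if dropped_expr or dropped_surv:
        logger.info(
            "dropped %d expression-only and %d survival-only samples",
            len(dropped_expr), len(dropped_surv),
        )

    expr = expr[common].apply(pd.to_numeric, errors="coerce")
    missing = expr.isna().any(axis=1)
    dropped_genes = expr.index[missing].tolist()
    if dropped_genes:
        logger.info("dropped %d genes with missing values", len(dropped_genes))
        expr = expr.loc[~missing]

    surv = surv.set_index("sample").loc[common]
    dataset = SurvivalDataset(
        time=surv["time"].to_numpy(dtype=float),
        event=surv["event"].to_numpy(),
        covariates=expr.to_numpy(dtype=float),
        subject_ids=common,
        gene_ids=[str(g) for g in expr.index],
    )
    return StudyBundle(
        path=str(expr_path),
        dataset=dataset,
        dropped_expr_samples=dropped_expr,
        dropped_surv_samples=dropped_surv,
        dropped_genes=dropped_genes,
    )


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene result table: TSV, 6 significant digits, sorted by
    index descending then gene id (stable)."""
    out = results.copy()
    sort_cols = [c for c in ("index", "gene") if c in out.columns]
    if "index" in out.columns:
        out = out.sort_values(
            sort_cols, ascending=[False, True][: len(sort_cols)], kind="stable"
        )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_study(dataset: SurvivalDataset, out_dir: str | Path,
                truth: np.ndarray | None = None) -> None:
    """Write ``expr.tsv`` + ``surv.tsv`` (+ ``truth.tsv``) for one study."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = pd.DataFrame(dataset.covariates, index=dataset.gene_ids,
                        columns=dataset.subject_ids)
    expr.index.name = "gene"
    expr.to_csv(out / "expr.tsv", sep="\t")
    surv = pd.DataFrame(
        {"sample": dataset.subject_ids, "time": dataset.time,
         "event": dataset.event}
    )
    surv.to_csv(out / "surv.tsv", sep="\t", index=False)
    if truth is not None:
        pd.DataFrame(
            {"gene": dataset.gene_ids, "prognostic": truth.astype(int)}
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
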