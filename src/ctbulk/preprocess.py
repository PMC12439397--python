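"""QC filtering, normalization, variable-gene selection, the per-patient
centering stand-in for integration, and imputation masking.

The masking step is the pivot of the whole pipeline: after integration the
expression matrix is dense, but every entry whose raw count was zero is an
artificial (imputed) value.  ``mask_imputed`` marks exactly those entries as
missing so that no downstream statistic ever consumes an imputed number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellExpressionMatrix, MaskedMatrix, check_annotation

__all__ = [
    "QCParams",
    "qc_filter_cells",
    "exclude_small_samples",
    "lognormalize",
    "select_variable_genes",
    "center_by_batch",
    "mask_imputed",
]


@dataclass
class QCParams:
    """Cell- and sample-level quality-control thresholds.

    Gene/count bounds are inclusive; the mitochondrial criterion is strict
    (fraction must be < ``max_mito_frac``).  ``min_cells_focal_type`` is the
    minimum number of cells of ``focal_cell_type`` (typically the tumor
    population) a patient must contribute to stay in the cohort.
    """

    min_genes: int = 500
    max_genes: int = 10_000
    min_counts: int = 1_000
    max_counts: int = 60_000
    max_mito_frac: float = 0.10
    min_cells_focal_type: int = 100
    focal_cell_type: str = "tumor"

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must not exceed max_genes")
        if self.min_counts > self.max_counts:
            raise ValueError("min_counts must not exceed max_counts")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must lie in [0, 1]")


def qc_filter_cells(
    m: CellExpressionMatrix, ann: pd.DataFrame, p: QCParams
) -> tuple[CellExpressionMatrix, pd.DataFrame]:
    """Keep cells with detected-gene and total-count numbers inside the
    inclusive bounds and a mitochondrial read fraction below the cutoff.

    Cell order is preserved.  Requires mito flags in ``m.genes`` whenever the
    mito criterion can exclude anything.
    """
    check_annotation(ann)
    mito = m.genes["mito"].to_numpy(dtype=bool)
    if p.max_mito_frac < 1.0 and not mito.any():
        raise ValueError(
            "no genes flagged mitochondrial: cannot evaluate the "
            "mito-fraction criterion (set max_mito_frac=1.0 to disable)"
        )
    csc = m.values.tocsc()
    csc.eliminate_zeros()
    n_detected = np.diff(csc.indptr)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    mito_counts = np.asarray(csc[mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = (
        (n_detected >= p.min_genes)
        & (n_detected <= p.max_genes)
        & (totals >= p.min_counts)
        & (totals <= p.max_counts)
        & (mito_frac < p.max_mito_frac)
    )
    return m.subset_cells(keep), ann.loc[m.cells[keep]]


def exclude_small_samples(
    m: CellExpressionMatrix, ann: pd.DataFrame, p: QCParams
) -> tuple[CellExpressionMatrix, pd.DataFrame, list[str]]:
    """Drop every cell of patients contributing fewer than
    ``min_cells_focal_type`` cells of the focal cell type."""
    check_annotation(ann)
    if p.focal_cell_type not in set(ann["cell_type"]):
        raise ValueError(
            f"focal cell type {p.focal_cell_type!r} absent from annotation"
        )
    focal = ann[ann["cell_type"] == p.focal_cell_type].groupby("patient").size()
    counts = focal.reindex(ann["patient"].unique(), fill_value=0)
    excluded = sorted(counts.index[counts < p.min_cells_focal_type])
    if len(excluded) == len(counts):
        warnings.warn("exclude_small_samples removed every patient")
    keep = ~ann["patient"].isin(excluded).to_numpy()
    return m.subset_cells(keep), ann.loc[m.cells[keep]], excluded


def lognormalize(m: CellExpressionMatrix, scale: float = 1e4) -> CellExpressionMatrix:
    """Library-size normalization: value = ln(1 + count * scale / cell_total).

    Zeros stay zeros, so the sparse structure is preserved.
    """
    csc = m.values.tocsc().astype(float)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = m.cells[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; filter before "
                         "normalizing")
    csc.data *= np.repeat(scale / totals, np.diff(csc.indptr))
    csc.data = np.log1p(csc.data)
    return CellExpressionMatrix(csc.tocsr(), m.genes, m.cells)


def select_variable_genes(m: CellExpressionMatrix, n_hvg: int) -> list[str]:
    """Top ``n_hvg`` genes by dispersion standardized within mean bins.

    Genes are binned into 20 equal-occupancy bins of per-gene mean
    (normalized values); within each bin the per-gene variance is z-scored,
    and genes are ranked by that standardized dispersion.  Ties break by
    gene id, so the selection is deterministic.
    """
    if n_hvg >= m.n_genes:
        if n_hvg > m.n_genes:
            warnings.warn(
                f"n_hvg={n_hvg} exceeds {m.n_genes} genes; returning all genes"
            )
        return list(m.genes.index)
    dense = np.asarray(m.values.todense())
    means = dense.mean(axis=1)
    variances = dense.var(axis=1, ddof=1)
    order = np.argsort(means, kind="stable")
    n_bins = max(1, min(20, m.n_genes // 2))  # bins need >= 2 genes
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.arange(m.n_genes) * n_bins // m.n_genes
    z = np.zeros(m.n_genes)
    for b in range(n_bins):
        sel = bins == b
        v = variances[sel]
        sd = v.std(ddof=1) if sel.sum() > 1 else 0.0
        z[sel] = (v - v.mean()) / sd if sd > 0 else v - v.mean()
    rank = pd.DataFrame({"z": z, "gene": m.genes.index})
    rank = rank.sort_values(["z", "gene"], ascending=[False, True])
    return rank["gene"].head(n_hvg).tolist()


def center_by_batch(m: CellExpressionMatrix, ann: pd.DataFrame) -> MaskedMatrix:
    """Per-patient gene centering over nonzero entries: a deliberately simple
    batch-alignment stand-in.  Zero entries pass through untouched (they are
    the candidates for masking); the output mask is empty until
    ``mask_imputed`` is applied.
    """
    check_annotation(ann)
    dense = np.asarray(m.values.todense(), dtype=float)
    nonzero = dense != 0
    for patient, sub in ann.groupby("patient"):
        cols = m.cells.get_indexer(sub.index)
        blk = dense[:, cols]
        obs = nonzero[:, cols]
        n = obs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (blk * obs).sum(axis=1) / np.maximum(n, 1), 0.0)
        dense[:, cols] = np.where(obs, blk - mean[:, None], blk)
    return MaskedMatrix(dense, np.zeros(dense.shape, dtype=bool),
                        m.genes.index, m.cells, provenance="integrated")


def mask_imputed(
    expr: CellExpressionMatrix | MaskedMatrix, raw: CellExpressionMatrix
) -> MaskedMatrix:
    """Mark every entry whose raw count is zero as missing.

    ``expr`` holds the processed (normalized or integration-centered) values;
    ``raw`` the original counts on the same gene/cell index sets.  Entries
    with a positive raw count keep their processed value; the missing
    fraction of the output equals the raw zero fraction exactly.
    """
    expr_genes = expr.genes.index if isinstance(expr, CellExpressionMatrix) else expr.genes
    if not (expr_genes.equals(raw.genes.index) and expr.cells.equals(raw.cells)):
        raise ValueError("expr and raw must share gene and cell index sets")
    raw_dense = np.asarray(raw.values.todense())
    mask = raw_dense == 0
    if isinstance(expr, CellExpressionMatrix):
        values = np.asarray(expr.values.todense(), dtype=float)
        provenance = "normalized-masked"
    else:
        values = np.array(expr.values, dtype=float, copy=True)
        provenance = ("integrated-masked" if expr.provenance.startswith("integrated")
                      else f"{expr.provenance}-masked")
    return MaskedMatrix(values, mask, expr_genes, raw.cells, provenance=provenance)
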