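"""Aggregation of masked single-cell expression into patient x cell-type
pseudobulk profiles, simulated bulk, and dotplot summaries.

The mean is taken over *observed* (non-missing) cells only, and an entry is
reported only when at least ``min_cells`` observed cells support it — the
support rule that restores sample-level replication on heavily masked data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import MaskedMatrix, PseudobulkTensor, check_annotation

__all__ = ["aggregate", "simulated_bulk", "dotplot_summary"]


def aggregate(
    m: MaskedMatrix, ann: pd.DataFrame, min_cells: int = 10
) -> PseudobulkTensor:
    """Mean expression per (cell type, gene, patient) over observed cells.

    Entries supported by fewer than ``min_cells`` observed cells are missing
    (``NaN``); the supporting-cell counts are recorded alongside.
    """
    check_annotation(ann)
    if not m.cells.equals(ann.index):
        ann = ann.loc[m.cells]
    patients = list(dict.fromkeys(ann["patient"]))
    groups = ann.drop_duplicates("patient").set_index("patient")["group"]
    obs = ~m.mask
    filled = np.where(m.mask, 0.0, m.values)

    values: dict[str, pd.DataFrame] = {}
    support: dict[str, pd.DataFrame] = {}
    for ct in dict.fromkeys(ann["cell_type"]):
        sub = ann[ann["cell_type"] == ct]
        if sub.empty:
            warnings.warn(f"cell type {ct!r} has no cells; dropped")
            continue
        cols = m.cells.get_indexer(sub.index)
        # patient indicator (cells x patients) for one matrix-product sweep
        pat_codes = pd.Categorical(sub["patient"], categories=patients).codes
        indic = np.zeros((len(cols), len(patients)))
        indic[np.arange(len(cols)), pat_codes] = 1.0
        sums = filled[:, cols] @ indic
        counts = (obs[:, cols] @ indic).astype(int)
        with np.errstate(invalid="ignore"):
            means = np.where(counts >= min_cells, sums / np.maximum(counts, 1),
                             np.nan)
        values[ct] = pd.DataFrame(means, index=m.genes, columns=patients)
        support[ct] = pd.DataFrame(counts, index=m.genes, columns=patients)
    return PseudobulkTensor(values, support, groups.loc[patients],
                            min_cells=min_cells)


def simulated_bulk(
    pb: PseudobulkTensor, eps: float = 1e-9
) -> tuple[pd.DataFrame, pd.Series]:
    """Bulk-like profiles by summing per-cell-type averages per patient.

    Missing entries contribute 0 (a patient lacking a cell type adds nothing
    to its simulated tissue).  The per-gene group log2 fold change is
    ``log2((mean_A + eps) / (mean_B + eps))`` over patients.
    """
    if not pb.values:
        raise ValueError("empty pseudobulk tensor")
    cts = pb.cell_types
    bulk = sum(pb.values[ct].fillna(0.0) for ct in cts)
    levels = sorted(set(pb.groups))
    if len(levels) != 2:
        raise ValueError(f"expected two groups, found {levels}")
    a_cols = [p for p in bulk.columns if pb.groups[p] == levels[0]]
    b_cols = [p for p in bulk.columns if pb.groups[p] == levels[1]]
    log2fc = np.log2((bulk[a_cols].mean(axis=1) + eps)
                     / (bulk[b_cols].mean(axis=1) + eps))
    log2fc.name = "log2fc"
    return bulk, log2fc


def dotplot_summary(
    pb: PseudobulkTensor,
    genes: list[str],
    cell_types: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per (gene, cell type, group): mean over expressing patients and the
    fraction of patients with an observed entry (the dot size of the
    classic dotplot).  Unknown genes are reported, not fatal.
    """
    cts = cell_types if cell_types is not None else pb.cell_types
    known_genes = set()
    for ct in cts:
        known_genes.update(pb.values[ct].index)
    skipped = [g for g in genes if g not in known_genes]
    rows = []
    group_levels = sorted(set(pb.groups))
    for ct in cts:
        frame = pb.values[ct]
        for g in genes:
            if g not in frame.index:
                continue
            row = frame.loc[g]
            for grp in group_levels:
                pats = [p for p in frame.columns if pb.groups[p] == grp]
                vals = row[pats]
                n_obs = int(vals.notna().sum())
                rows.append({
                    "gene": g,
                    "cell_type": ct,
                    "group": grp,
                    "mean_expr": float(vals.mean()) if n_obs else np.nan,
                    "frac_patients": n_obs / len(pats) if pats else np.nan,
                })
    return pd.DataFrame(rows), skipped
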