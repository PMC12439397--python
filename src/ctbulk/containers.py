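"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Expression matrices are genes x cells (rows = genes), matching the
  on-disk Matrix Market layout of 10x-style directories.
* Missingness is explicit: a masked entry carries no value and is distinct
  from an observed zero.  Sparse count matrices have no mask (a stored zero
  and an absent triplet mean the same thing); masked dense matrices carry a
  boolean ``mask`` with ``True`` = missing.
* Pseudobulk tensors use ``NaN`` for missing entries in their per-cell-type
  gene x patient frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellExpressionMatrix",
    "MaskedMatrix",
    "PseudobulkTensor",
    "DEResult",
    "SimTruth",
]

#: Required columns of a cell annotation frame (indexed by barcode).
ANNOTATION_COLUMNS = ("patient", "group", "cell_type")


def check_annotation(ann: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"cell annotation lacks required column(s): {missing}")


@dataclass
class CellExpressionMatrix:
    """Sparse genes x cells expression values (counts or normalized).

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix, shape ``(n_genes, n_cells)``.
    genes
        Frame indexed by gene id with at least columns ``symbol`` and
        ``mito`` (bool flag for mitochondrial genes).
    cells
        Barcode index, aligned with the matrix columns.
    """

    values: sp.spmatrix
    genes: pd.DataFrame
    cells: pd.Index

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if not isinstance(self.cells, pd.Index):
            self.cells = pd.Index(self.cells)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.genes.index.has_duplicates:
            dups = self.genes.index[self.genes.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, keep: np.ndarray) -> "CellExpressionMatrix":
        """Column subset preserving order; ``keep`` is a boolean or integer indexer."""
        return CellExpressionMatrix(
            self.values[:, keep], self.genes, self.cells[keep]
        )


@dataclass
class MaskedMatrix:
    """Dense genes x cells values with an explicit missing-entry mask.

    ``mask[i, j] is True`` means entry (i, j) is missing: its value slot is
    meaningless and must not be consumed downstream.  ``provenance`` records
    which pipeline branch produced the values ("normalized" or
    "integrated-masked").
    """

    values: np.ndarray
    mask: np.ndarray
    genes: pd.Index
    cells: pd.Index
    provenance: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("mask dimensions must equal value dimensions")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match gene/cell index lengths")
        # a masked slot carries no value
        self.values = np.where(self.mask, np.nan, self.values)

    @property
    def missing_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class PseudobulkTensor:
    """Per-cell-type gene x patient aggregate with per-entry supporting-cell counts.

    ``values[ct]`` is a genes x patients frame with ``NaN`` where fewer than
    ``min_cells`` observed cells supported the mean; ``support[ct]`` holds the
    integer count of observed (non-missing) cells behind each entry.
    ``groups`` maps patient id -> group label.
    """

    values: dict[str, pd.DataFrame]
    support: dict[str, pd.DataFrame]
    groups: pd.Series
    min_cells: int = 10

    def __post_init__(self) -> None:
        for ct, frame in self.values.items():
            sup = self.support[ct]
            if frame.shape != sup.shape:
                raise ValueError(f"{ct}: value/support shape mismatch")
            present = ~frame.isna().to_numpy()
            if (sup.to_numpy()[present] < self.min_cells).any():
                raise ValueError(f"{ct}: present entry with support < min_cells")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values)

    def patients_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class DEResult:
    """Differential-expression output across cell types.

    ``table`` has one row per (cell_type, gene) with columns: n_A, n_B,
    mean_A, mean_B, log2fc, s2, df, t, p, fdr.  ``priors`` maps cell type to
    the empirical-Bayes hyperparameters ``(d0, s0_sq)`` (``d0`` may be
    ``inf``).  ``summary`` counts significant genes per cell type x FDR
    cutoff x direction.
    """

    table: pd.DataFrame
    priors: dict[str, tuple[float, float]]
    summary: pd.DataFrame | None = None

    def for_cell_type(self, ct: str) -> pd.DataFrame:
        sub = self.table[self.table["cell_type"] == ct]
        if sub.empty:
            raise KeyError(f"cell type {ct!r} was not tested")
        return sub


@dataclass
class SimTruth:
    """Planted ground truth of a simulated dataset.

    ``de_genes`` rows: (gene, cell_type, log2_effect); ``null_cell_types``
    are cell types with no planted effects (includes the designated tumor
    type under the default template); ``homogeneity`` is the pair
    (patient_effect_sd_A, patient_effect_sd_B).
    """

    de_genes: pd.DataFrame
    null_cell_types: list[str]
    homogeneity: tuple[float, float]
    tumor_cell_type: str = "tumor"

    def planted(self, cell_type: str) -> pd.DataFrame:
        return self.de_genes[self.de_genes["cell_type"] == cell_type]
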