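"""On-disk formats and run configuration.

A dataset directory follows the 10x-style triplet layout:

    matrix.mtx     Matrix Market coordinate values (1-based indices on disk,
                   0-based in memory), genes x cells
    features.tsv   gene_id, symbol, mito (0/1)
    barcodes.tsv   one barcode per line
    cells.tsv      barcode, patient, group, cell_type

Masked matrices are stored as a values/mask MTX pair (mask entries are the
missing positions).  Pseudobulk tensors become one genes x patients TSV per
cell type plus a supporting-cell-count TSV; missing entries are written as
the literal string "NA".  Floats are serialized with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .containers import CellExpressionMatrix, MaskedMatrix, PseudobulkTensor

__all__ = [
    "RunConfig",
    "GeneSetCollection",
    "read_cell_matrix",
    "write_cell_matrix",
    "read_masked_matrix",
    "write_masked_matrix",
    "write_pseudobulk",
    "read_pseudobulk",
    "read_gmt",
    "write_table",
]

logger = logging.getLogger("ctbulk")

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline in one place.

    Defaults are the full-scale analysis constants; the desk-scale QC
    bounds used with the synthetic template are much looser and live in the
    template config written by the ``simulate`` stage.
    """

    # QC
    min_genes: int = 500
    max_genes: int = 10_000
    min_counts: int = 1_000
    max_counts: int = 60_000
    max_mito_frac: float = 0.10
    min_cells_focal_type: int = 100
    focal_cell_type: str = "tumor"
    # normalization / feature selection / integration
    normalize_scale: float = 1e4
    n_hvg: int = 17_500
    integrate: bool = True
    # pseudobulk / DE
    min_cells: int = 10
    min_patients_per_group: int = 4
    fdr_cutoffs: list[float] = field(default_factory=lambda: [0.05, 0.1, 0.2])
    n_top_signature: int = 50
    # correlation
    n_cell_pairs: int = 100
    # clustering / PCA / enrichment
    n_boot: int = 1000
    n_components: int = 10
    n_perm: int = 1000
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_genes", "max_genes", "min_counts", "max_counts",
                     "min_cells", "min_patients_per_group", "n_top_signature",
                     "n_cell_pairs", "n_hvg", "n_boot", "n_components",
                     "n_perm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(not 0.0 < c < 1.0 for c in self.fdr_cutoffs):
            raise ValueError("fdr_cutoffs must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members or any(not isinstance(g, str) or not g
                                  for g in members):
                raise ValueError(f"set {name!r} has empty or non-string members")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name, description, members, tab-separated.

    Duplicate members within a set are deduplicated; a line with fewer than
    3 fields is an error naming the line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}: line {lineno} has {len(parts)} field(s); "
                "GMT requires name, description and >= 1 member"
            )
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r} "
                             f"(line {lineno})")
        members = {g for g in parts[2:] if g}
        if not members:
            raise ValueError(f"{path}: set {name!r} has no members "
                             f"(line {lineno})")
        sets[name] = members
        descriptions[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_cell_matrix(
    m: CellExpressionMatrix, ann: pd.DataFrame, out_dir: str | Path
) -> None:
    """Write the triplet layout; ordering (genes then cells as given) and
    float formatting are deterministic, so re-writing read output is
    byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coo = m.values.tocoo()
    order = np.lexsort((coo.col, coo.row))
    canonical = sp.coo_matrix(
        (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
    )
    scipy.io.mmwrite(out / "matrix.mtx", canonical, precision=6)
    feat = m.genes.reset_index()
    feat.columns = ["gene_id", "symbol", "mito"]
    feat["mito"] = feat["mito"].astype(int)
    feat.to_csv(out / "features.tsv", sep="\t", index=False)
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in m.cells))
    ann.reset_index(names="barcode").to_csv(out / "cells.tsv", sep="\t",
                                            index=False)


def read_cell_matrix(
    dir_path: str | Path,
) -> tuple[CellExpressionMatrix, pd.DataFrame]:
    """Read a triplet directory back into matrix + annotation."""
    d = Path(dir_path)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv", "cells.tsv"):
        if not (d / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {d}")
    try:
        mat = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx"))
    except Exception as err:
        raise ValueError(f"malformed matrix.mtx in {d}: {err}") from err
    feat = pd.read_csv(d / "features.tsv", sep="\t")
    if feat["gene_id"].duplicated().any():
        dups = feat.loc[feat["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in features.tsv: {dups[:5]}")
    barcodes = pd.Index(
        (d / "barcodes.tsv").read_text().splitlines(), name="barcode"
    )
    if mat.shape != (len(feat), len(barcodes)):
        raise ValueError(
            f"matrix.mtx declares shape {mat.shape} but features.tsv lists "
            f"{len(feat)} genes and barcodes.tsv {len(barcodes)} cells"
        )
    genes = feat.set_index("gene_id")
    genes["mito"] = genes["mito"].astype(bool)
    cells_tab = pd.read_csv(d / "cells.tsv", sep="\t").set_index("barcode")
    unknown = set(cells_tab.index) - set(barcodes)
    if unknown:
        raise ValueError(
            f"cells.tsv contains barcode(s) absent from barcodes.tsv: "
            f"{sorted(unknown)[:5]}"
        )
    ann = cells_tab.reindex(barcodes)
    return CellExpressionMatrix(mat, genes, barcodes), ann


def write_masked_matrix(m: MaskedMatrix, out_dir: str | Path) -> None:
    """Masked matrix as a values/mask MTX pair plus index files.

    values.mtx stores the observed entries in coordinate form; mask.mtx
    stores a 1 at every missing position.  An entry in neither file is an
    observed zero.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs = ~m.mask
    vals = np.where(obs, np.nan_to_num(m.values), 0.0)
    scipy.io.mmwrite(out / "values.mtx", sp.coo_matrix(vals), precision=6)
    scipy.io.mmwrite(out / "mask.mtx",
                     sp.coo_matrix(m.mask.astype(np.int8)))
    (out / "genes.tsv").write_text("".join(f"{g}\n" for g in m.genes))
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in m.cells))
    (out / "provenance.txt").write_text(m.provenance + "\n")


def read_masked_matrix(dir_path: str | Path) -> MaskedMatrix:
    d = Path(dir_path)
    vals = np.asarray(scipy.io.mmread(d / "values.mtx").todense())
    mask = np.asarray(scipy.io.mmread(d / "mask.mtx").todense()).astype(bool)
    genes = pd.Index((d / "genes.tsv").read_text().splitlines(), name="gene")
    cells = pd.Index((d / "barcodes.tsv").read_text().splitlines(),
                     name="barcode")
    prov = (d / "provenance.txt").read_text().strip()
    return MaskedMatrix(vals, mask, genes, cells, provenance=prov)


def write_pseudobulk(pb: PseudobulkTensor, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ct in pb.cell_types:
        safe = ct.replace("/", "_")
        pb.values[ct].to_csv(out / f"values_{safe}.tsv", sep="\t",
                             na_rep="NA", float_format=FLOAT_FMT)
        pb.support[ct].to_csv(out / f"support_{safe}.tsv", sep="\t")
    pb.groups.rename("group").to_csv(out / "groups.tsv", sep="\t")
    (out / "min_cells.txt").write_text(f"{pb.min_cells}\n")
    (out / "cell_types.txt").write_text("".join(f"{ct}\n"
                                                for ct in pb.cell_types))


def read_pseudobulk(dir_path: str | Path) -> PseudobulkTensor:
    d = Path(dir_path)
    cts = (d / "cell_types.txt").read_text().splitlines()
    min_cells = int((d / "min_cells.txt").read_text().strip())
    groups = pd.read_csv(d / "groups.tsv", sep="\t", index_col=0)["group"]
    values, support = {}, {}
    for ct in cts:
        safe = ct.replace("/", "_")
        values[ct] = pd.read_csv(d / f"values_{safe}.tsv", sep="\t",
                                 index_col=0, na_values=["NA"])
        support[ct] = pd.read_csv(d / f"support_{safe}.tsv", sep="\t",
                                  index_col=0)
    return PseudobulkTensor(values, support, groups, min_cells=min_cells)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """TSV with header, "NA" for missing and 6-significant-digit floats."""
    frame.to_csv(path, sep="\t", index=index, na_rep="NA",
                 float_format=FLOAT_FMT)
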