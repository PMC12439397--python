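"""Shared fixtures: small hand-built matrices and one session-scoped sweep
of the default synthetic template through the analysis chain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ctbulk.containers import CellExpressionMatrix, MaskedMatrix
from ctbulk.correlation import fit_lmm_contrasts, pseudobulk_pair_correlations
from ctbulk.diffexp import DesignSpec, run_de
from ctbulk.preprocess import lognormalize, mask_imputed
from ctbulk.pseudobulk import aggregate
from ctbulk.structure import hcluster, signature_matrix, two_group_separation
from ctbulk.synthetic import default_study_template, simulate_dataset

N_SWEEP_SEEDS = 20


def make_cell_matrix(counts: np.ndarray, patients=None, groups=None,
                     cell_types=None, mito_flags=None) -> tuple:
    """Wrap a dense count array into matrix + annotation."""
    G, C = counts.shape
    genes = pd.DataFrame(
        {
            "symbol": [f"S{i}" for i in range(G)],
            "mito": mito_flags if mito_flags is not None else [False] * G,
        },
        index=pd.Index([f"G{i}" for i in range(G)], name="gene"),
    )
    barcodes = pd.Index([f"C{i}" for i in range(C)], name="barcode")
    ann = pd.DataFrame(
        {
            "patient": patients if patients is not None else ["P1"] * C,
            "group": groups if groups is not None else ["A"] * C,
            "cell_type": cell_types if cell_types is not None else ["t"] * C,
        },
        index=barcodes,
    )
    return CellExpressionMatrix(sp.csr_matrix(counts), genes, barcodes), ann


@dataclass
class TemplateRun:
    seed: int
    truth: object
    pb: object
    de: object
    corr_records: pd.DataFrame
    lmm_contrast_aa_bb: float
    union_perfect: bool
    tumor_perfect: bool
    zero_fraction: float


def _run_template(seed: int) -> TemplateRun:
    cfg = default_study_template(seed=seed)
    m, ann, truth = simulate_dataset(cfg)
    zero_fraction = 1.0 - m.values.nnz / (m.n_genes * m.n_cells)
    mm = mask_imputed(lognormalize(m), m)
    pb = aggregate(mm, ann, min_cells=10)
    de = run_de(pb, DesignSpec(groups=pb.groups))
    recs = pd.concat(
        [pseudobulk_pair_correlations(pb, ct) for ct in pb.cell_types],
        ignore_index=True,
    )
    fit = fit_lmm_contrasts(recs)
    con = fit.contrasts
    aa_bb = float(
        con[(con.class_1 == "A-A") & (con.class_2 == "B-B")].estimate.iloc[0]
    )
    union = two_group_separation(
        hcluster(signature_matrix(pb, de, pb.cell_types, k=50)), pb.groups
    )["perfect"]
    tumor = two_group_separation(
        hcluster(signature_matrix(pb, de, ["tumor"], k=50)), pb.groups
    )["perfect"]
    return TemplateRun(seed, truth, pb, de, recs, aa_bb, union, tumor,
                       zero_fraction)


@pytest.fixture(scope="session")
def template_sweep() -> list[TemplateRun]:
    """The default template analyzed end to end for 20 seeds; shared by the
    recovery-style acceptance checks."""
    return [_run_template(seed) for seed in range(N_SWEEP_SEEDS)]


@pytest.fixture(scope="session")
def template_run_once(template_sweep) -> TemplateRun:
    return template_sweep[0]


@pytest.fixture()
def small_masked() -> tuple[MaskedMatrix, pd.DataFrame]:
    """8 genes x 30 cells, 2 patients x 2 cell types, ~30% masked."""
    rng = np.random.default_rng(11)
    G, C = 8, 30
    values = rng.gamma(2.0, 1.0, size=(G, C))
    mask = rng.random((G, C)) < 0.3
    genes = pd.Index([f"G{i}" for i in range(G)], name="gene")
    cells = pd.Index([f"C{i}" for i in range(C)], name="barcode")
    ann = pd.DataFrame(
        {
            "patient": ["P1"] * 15 + ["P2"] * 15,
            "group": ["A"] * 15 + ["B"] * 15,
            "cell_type": (["t1"] * 8 + ["t2"] * 7) * 2,
        },
        index=cells,
    )
    return MaskedMatrix(values, mask, genes, cells), ann
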