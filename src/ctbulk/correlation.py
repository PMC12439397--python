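"""Expression-profile homogeneity within and between patient groups.

Pairwise Pearson correlations between patients' pseudobulk profiles (and,
at single-cell resolution, between randomly drawn cross-sample cell pairs)
are classified as A-A, B-B or A-B pairs.  Group differences are tested two
ways: Welch t-tests between the per-class correlation distributions, and a
random-intercept linear mixed model

    r ~ pair_class + (1 | patient_pair)

fit by REML with a profiled one-dimensional search over the variance ratio
sigma_u^2 / sigma_e^2, followed by pairwise contrasts between the class
means with normal-approximation p-values and BH correction.

All Pearson computations are pairwise-complete: masked entries are dropped
per pair, and pairs sharing fewer than ``MIN_SHARED_GENES`` observed genes
are not scored.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MaskedMatrix, PseudobulkTensor, check_annotation
from .diffexp import bh_fdr

__all__ = [
    "MIN_SHARED_GENES",
    "pseudobulk_pair_correlations",
    "compare_correlation_groups",
    "sample_cellpair_correlations",
    "LMMFit",
    "fit_lmm_contrasts",
]

MIN_SHARED_GENES = 10


def _pair_class(gi: str, gj: str) -> str:
    a, b = sorted((gi, gj))
    return f"{a}-{b}"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def pseudobulk_pair_correlations(pb: PseudobulkTensor, ct: str) -> pd.DataFrame:
    """Pearson r for every unordered patient pair of one cell type, over
    genes observed in both patients."""
    if ct not in pb.values:
        raise KeyError(f"cell type {ct!r} not in tensor")
    frame = pb.values[ct]
    patients = [p for p in frame.columns if frame[p].notna().sum() > 0]
    if len(patients) < 2:
        warnings.warn(f"{ct}: fewer than 2 patients with entries")
        return pd.DataFrame(
            columns=["cell_type", "patient_i", "patient_j", "pair_class", "r", "n"]
        )
    rows = []
    vals = frame[patients].to_numpy()
    obs = ~np.isnan(vals)
    for ai, bi in itertools.combinations(range(len(patients)), 2):
        shared = obs[:, ai] & obs[:, bi]
        if shared.sum() < MIN_SHARED_GENES:
            warnings.warn(
                f"{ct}: pair ({patients[ai]}, {patients[bi]}) shares "
                f"{int(shared.sum())} genes (< {MIN_SHARED_GENES}); dropped"
            )
            continue
        r = _pearson(vals[shared, ai], vals[shared, bi])
        rows.append({
            "cell_type": ct,
            "patient_i": patients[ai],
            "patient_j": patients[bi],
            "pair_class": _pair_class(pb.groups[patients[ai]],
                                      pb.groups[patients[bi]]),
            "r": r,
            "n": int(shared.sum()),
        })
    return pd.DataFrame(rows)


def compare_correlation_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Welch t-tests between pair-class correlation distributions.

    All class pairs with >= 2 records and nonzero variance on both sides are
    tested per cell type; BH FDR is applied across every performed test.
    Stars: '*' at FDR < 0.05, '***' at FDR < 0.001.
    """
    rows = []
    for ct, sub in records.groupby("cell_type"):
        classes = sorted(sub["pair_class"].unique())
        for c1, c2 in itertools.combinations(classes, 2):
            r1 = sub.loc[sub["pair_class"] == c1, "r"].dropna()
            r2 = sub.loc[sub["pair_class"] == c2, "r"].dropna()
            row = {"cell_type": ct, "class_1": c1, "class_2": c2,
                   "n_1": len(r1), "n_2": len(r2),
                   "mean_1": r1.mean(), "mean_2": r2.mean()}
            if len(r1) < 2 or len(r2) < 2:
                row.update(t=np.nan, p=np.nan, skipped="too_few_records")
            elif r1.std() == 0 and r2.std() == 0:
                row.update(t=np.nan, p=np.nan, skipped="zero_variance")
            else:
                t, p = stats.ttest_ind(r1, r2, equal_var=False)
                row.update(t=float(t), p=float(p), skipped="")
            rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    tested = table["p"].notna()
    table["fdr"] = np.nan
    if tested.any():
        table.loc[tested, "fdr"] = bh_fdr(table.loc[tested, "p"].to_numpy())
    table["stars"] = np.where(table["fdr"] < 0.001, "***",
                              np.where(table["fdr"] < 0.05, "*", ""))
    return table


def sample_cellpair_correlations(
    m: MaskedMatrix,
    ann: pd.DataFrame,
    ct: str,
    n_pairs: int = 100,
    seed: int = 0,
    max_retries: int = 10,
) -> pd.DataFrame:
    """Single-cell resolution homogeneity: for every unordered sample pair,
    average the Pearson correlation of ``n_pairs`` random cross-sample cell
    pairs (one cell from each sample, drawn with replacement).

    Draws sharing fewer than ``MIN_SHARED_GENES`` observed genes are redrawn
    up to ``max_retries * n_pairs`` times in total; a sample pair whose
    draws cannot be scored is skipped.
    """
    check_annotation(ann)
    rng = np.random.default_rng(seed)
    sub = ann[ann["cell_type"] == ct]
    patients = list(dict.fromkeys(sub["patient"]))
    cols = {p: m.cells.get_indexer(sub.index[sub["patient"] == p])
            for p in patients}
    groups = sub.drop_duplicates("patient").set_index("patient")["group"]
    obs = ~m.mask
    rows = []
    for pi, pj in itertools.combinations(patients, 2):
        ci, cj = cols[pi], cols[pj]
        if len(ci) == 0 or len(cj) == 0:
            continue
        n_target = min(n_pairs, len(ci) * len(cj))
        rs: list[float] = []
        attempts = 0
        while len(rs) < n_target and attempts < max_retries * n_pairs:
            attempts += 1
            a = ci[rng.integers(len(ci))]
            b = cj[rng.integers(len(cj))]
            shared = obs[:, a] & obs[:, b]
            if shared.sum() < MIN_SHARED_GENES:
                continue
            r = _pearson(m.values[shared, a], m.values[shared, b])
            if np.isfinite(r):
                rs.append(r)
        if not rs:
            warnings.warn(f"{ct}: sample pair ({pi}, {pj}) skipped "
                          "(no scorable cell pairs)")
            continue
        rows.append({
            "cell_type": ct, "patient_i": pi, "patient_j": pj,
            "pair_class": _pair_class(groups[pi], groups[pj]),
            "r": float(np.mean(rs)), "n": len(rs),
        })
    return pd.DataFrame(rows)


@dataclass
class LMMFit:
    """Random-intercept model fit and pairwise class contrasts."""

    class_means: pd.Series
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float
    contrasts: pd.DataFrame
    boundary: bool = False
    cov_means: pd.DataFrame | None = None


def _reml_neg2loglik(lam: float, y, X, Z):
    n, p = X.shape
    V = np.eye(n) + lam * (Z @ Z.T)
    sign, logdet_v = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    quad = float(resid @ Vi @ resid)
    if quad <= 0:
        quad = np.finfo(float).tiny
    return (logdet_v + logdet_x + (n - p) * np.log(quad), beta, XtViX, quad)


def fit_lmm_contrasts(
    records: pd.DataFrame, lambda_override: float | None = None
) -> LMMFit:
    """REML fit of r ~ pair_class + (1 | patient_pair) with pairwise class
    contrasts.

    The random-effect grouping has one level per unordered patient pair,
    shared across cell types when records from several cell types are fit
    jointly.  The variance ratio is profiled on a bounded one-dimensional
    REML search; a boundary fit sigma_u^2 = 0 is valid and flagged.
    ``lambda_override`` pins the ratio sigma_u^2/sigma_e^2 (0 reduces the
    fit to ordinary least squares).  Contrast p-values use the normal
    approximation and BH correction.
    """
    rec = records.dropna(subset=["r"]).copy()
    classes = sorted(rec["pair_class"].unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 pair classes for contrasts")
    y = rec["r"].to_numpy(float)
    X = pd.get_dummies(rec["pair_class"]).loc[:, classes].to_numpy(float)
    pair_ids = rec["patient_i"].astype(str) + "|" + rec["patient_j"].astype(str)
    Z = pd.get_dummies(pair_ids).to_numpy(float)
    n, p = X.shape

    if np.allclose(y, y[0]):
        means = pd.Series(y[0], index=classes)
        contrasts = _contrast_table(means, None, 0.0, classes, degenerate=True)
        return LMMFit(means, 0.0, 0.0, np.nan, contrasts, boundary=True)

    def objective(log_lam: float) -> float:
        return _reml_neg2loglik(np.exp(log_lam), y, X, Z)[0]

    if lambda_override is not None:
        lam = float(lambda_override)
        crit, beta, XtViX, quad = _reml_neg2loglik(lam, y, X, Z)
        boundary = lam == 0.0
    else:
        # coarse profile on a log grid, then local refinement
        grid = np.linspace(-10.0, 6.0, 33)
        vals = [objective(g) for g in grid]
        best = int(np.argmin(vals))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(objective, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        if not res.success:
            raise RuntimeError(f"REML profile failed to converge: {res}")
        lam = float(np.exp(res.x))
        crit0, beta0, XtViX0, quad0 = _reml_neg2loglik(0.0, y, X, Z)
        crit, beta, XtViX, quad = _reml_neg2loglik(lam, y, X, Z)
        boundary = crit0 <= crit + 1e-10
        if boundary:
            lam, crit, beta, XtViX, quad = 0.0, crit0, beta0, XtViX0, quad0
    sigma2_e = quad / (n - p)
    sigma2_u = lam * sigma2_e
    cov_beta = sigma2_e * np.linalg.inv(XtViX)

    means = pd.Series(beta, index=classes)
    cov_means = pd.DataFrame(cov_beta, index=classes, columns=classes)
    contrasts = _contrast_table(means, cov_means, sigma2_e, classes)
    return LMMFit(means, float(sigma2_u), float(sigma2_e), -0.5 * crit,
                  contrasts, boundary=bool(boundary), cov_means=cov_means)


def _contrast_table(means, cov_means, sigma2_e, classes, degenerate=False):
    rows = []
    for c1, c2 in itertools.combinations(classes, 2):
        est = float(means[c1] - means[c2])
        if degenerate or cov_means is None:
            se, z, pval = 0.0, np.nan, 1.0
        else:
            se = float(np.sqrt(cov_means.loc[c1, c1] + cov_means.loc[c2, c2]
                               - 2.0 * cov_means.loc[c1, c2]))
            z = est / se if se > 0 else np.nan
            pval = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 1.0
        rows.append({"class_1": c1, "class_2": c2, "estimate": est,
                     "se": se, "z": z, "p": pval})
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    return table
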