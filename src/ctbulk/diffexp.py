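"""Cell-type-wise two-group differential expression on pseudobulk profiles
with an empirical-Bayes moderated t-statistic.

Per cell type and gene, an ordinary least-squares fit of the aggregated
log-normalized expression on [intercept, group, covariates...] over that
gene's observed patients yields a group coefficient, residual variance
s_g^2 and residual degrees of freedom d_g.  The per-gene variances are then
shrunk toward a common prior: assuming s_g^2 | sigma_g^2 ~ sigma_g^2
chi^2_{d_g}/d_g with a scaled inverse-chi^2 prior sigma_g^2 ~ d0 s0^2 /
chi^2_{d0}, the posterior variance is

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

and t = beta_g / sqrt(s~_g^2 v_g) follows a t distribution with d0 + d_g
degrees of freedom.  The hyperparameters (d0, s0^2) are estimated by
moment-matching the log residual variances against digamma/trigamma
identities of the scaled-F marginal of s_g^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import DEResult, PseudobulkTensor

__all__ = [
    "DesignSpec",
    "eligible_genes",
    "fit_linear_models",
    "ebayes_moderate",
    "trigamma_inverse",
    "bh_fdr",
    "run_de",
    "top_signature_genes",
]

#: d0 values above this are reported as infinite (complete shrinkage).
D0_CAP = 1e6


@dataclass
class DesignSpec:
    """Two-group design with optional covariates.

    ``groups`` maps patient -> group label (exactly two levels; the
    alphabetically first is the reference, so the group coefficient is
    "second level minus first").  ``covariates`` is an optional patients x k
    frame; ``min_patients_per_group`` is the per-gene eligibility rule
    (4 default; 3 for the reduced-cohort variant).
    """

    groups: pd.Series
    covariates: pd.DataFrame | None = None
    min_patients_per_group: int = 4
    fdr_cutoffs: tuple[float, ...] = (0.05, 0.1, 0.2)

    def __post_init__(self) -> None:
        levels = sorted(set(self.groups))
        if len(levels) != 2:
            raise ValueError(f"need exactly two group levels, got {levels}")
        self.levels = levels
        if self.covariates is not None:
            missing = set(self.groups.index) - set(self.covariates.index)
            if missing:
                raise ValueError(f"covariates missing for patients {sorted(missing)}")

    def matrix(self, patients: list[str]) -> np.ndarray:
        """Design matrix rows for ``patients``: intercept, group indicator,
        then covariates."""
        ind = (self.groups.loc[patients] == self.levels[1]).to_numpy(float)
        cols = [np.ones(len(patients)), ind]
        if self.covariates is not None:
            for c in self.covariates.columns:
                cols.append(self.covariates.loc[patients, c].to_numpy(float))
        return np.column_stack(cols)


def eligible_genes(pb: PseudobulkTensor, ct: str, design: DesignSpec) -> list[str]:
    """Genes with observed pseudobulk entries in at least
    ``min_patients_per_group`` patients of *both* groups."""
    if ct not in pb.values:
        raise KeyError(f"cell type {ct!r} not in tensor")
    frame = pb.values[ct]
    ok = np.ones(len(frame), dtype=bool)
    for level in design.levels:
        pats = [p for p in frame.columns if design.groups.get(p) == level]
        ok &= (frame[pats].notna().sum(axis=1) >= design.min_patients_per_group
               ).to_numpy()
    return list(frame.index[ok])


def fit_linear_models(
    pb: PseudobulkTensor, ct: str, design: DesignSpec, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene OLS over that gene's observed patients.

    Returns a frame indexed by gene with columns: coef (group effect on the
    input scale), log2fc (coef / ln 2, the fold change of the second group
    level over the first when inputs are natural-log values), s2, df, v
    (design-based unscaled variance of the group coefficient), n_A, n_B,
    mean_A, mean_B.  Genes with nonpositive residual df are dropped with a
    warning.
    """
    frame = pb.values[ct]
    if genes is None:
        genes = eligible_genes(pb, ct, design)
    rows = {}
    dropped = []
    ln2 = np.log(2.0)
    for g in genes:
        y_all = frame.loc[g]
        pats = list(y_all.index[y_all.notna()])
        y = y_all[pats].to_numpy(float)
        X = design.matrix(pats)
        rank = np.linalg.matrix_rank(X)
        df = len(pats) - rank
        if df <= 0:
            dropped.append(g)
            continue
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / df
        xtx_inv = np.linalg.pinv(X.T @ X)
        grp = design.groups.loc[pats]
        in_b = grp == design.levels[1]
        rows[g] = {
            "coef": float(beta[1]),
            "log2fc": float(beta[1]) / ln2,
            "s2": s2,
            "df": float(df),
            "v": float(xtx_inv[1, 1]),
            "n_A": int((~in_b).sum()),
            "n_B": int(in_b.sum()),
            "mean_A": float(y[~in_b.to_numpy()].mean()),
            "mean_B": float(y[in_b.to_numpy()].mean()),
        }
    if dropped:
        warnings.warn(f"{ct}: {len(dropped)} gene(s) dropped "
                      "(no residual degrees of freedom)")
    return pd.DataFrame.from_dict(rows, orient="index")


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        tetra = float(special.polygamma(2, x))
        step = tri * (1.0 - tri / y) / tetra
        x = x + step
        if x <= 0:
            x = 1e-8
        if abs(step) < tol * max(x, 1.0):
            break
    return x


def ebayes_moderate(
    s2: np.ndarray,
    df: np.ndarray,
    d0_override: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Estimate the variance prior (d0, s0^2) and return the shrunken
    per-gene variances ``(d0 s0^2 + d s^2) / (d0 + d)``.

    ``d0_override`` forces the prior degrees of freedom (0 disables
    moderation; ``inf`` gives complete shrinkage to s0^2).
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2 and d0_override is None:
        warnings.warn("fewer than 2 usable variances: no moderation applied")
        return 0.0, float("nan"), s2.copy()

    # log-variance moments: E[log s^2] and Var[log s^2] under the scaled-F
    # marginal decompose into digamma/trigamma terms of d/2 and d0/2
    e = (np.log(s2[ok]) - special.digamma(df[ok] / 2.0)
         + np.log(df[ok] / 2.0))
    e_bar = float(e.mean())
    n = ok.sum()
    if d0_override is not None:
        d0 = float(d0_override)
        if np.isinf(d0):
            s0_sq = float(np.exp(e_bar))
        elif d0 == 0.0:
            s0_sq = float("nan")
        else:
            s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0)
                                 - np.log(d0 / 2.0)))
    else:
        ev = float(((e - e_bar) ** 2).sum() / (n - 1)) if n > 1 else 0.0
        resid_var = ev - float(special.polygamma(1, df[ok] / 2.0).mean())
        if resid_var <= 0:
            d0 = np.inf
        else:
            d0 = 2.0 * trigamma_inverse(resid_var)
        if d0 > D0_CAP:
            d0 = np.inf
        if np.isinf(d0):
            s0_sq = float(np.exp(e_bar))
        else:
            s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0)
                                 - np.log(d0 / 2.0)))

    if d0 == 0.0:
        s2_post = s2.copy()
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, s2_post


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _moderated_stats(
    fits: pd.DataFrame, d0: float, s2_post: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    denom = np.sqrt(s2_post * fits["v"].to_numpy())
    t = fits["coef"].to_numpy() / denom
    df_total = fits["df"].to_numpy() + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p


def run_de(
    pb: PseudobulkTensor,
    design: DesignSpec,
    d0_override: float | None = None,
) -> DEResult:
    """Full differential-expression pass over all cell types.

    Eligibility, per-gene OLS, empirical-Bayes moderation and BH FDR are
    applied within each cell type; the summary counts significant genes per
    cutoff and fold-change direction.
    """
    tables = []
    priors: dict[str, tuple[float, float]] = {}
    for ct in pb.cell_types:
        fits = fit_linear_models(pb, ct, design)
        if fits.empty:
            continue
        d0, s0_sq, s2_post = ebayes_moderate(
            fits["s2"].to_numpy(), fits["df"].to_numpy(), d0_override
        )
        t, p = _moderated_stats(fits, d0, s2_post)
        sub = fits.copy()
        sub.insert(0, "cell_type", ct)
        sub["s2_post"] = s2_post
        sub["t"] = t
        sub["p"] = p
        sub["fdr"] = bh_fdr(p)
        priors[ct] = (d0, s0_sq)
        tables.append(sub.rename_axis("gene").reset_index())
    if not tables:
        raise ValueError("no cell type produced testable genes")
    table = pd.concat(tables, ignore_index=True)

    rows = []
    for ct in priors:
        sub = table[table["cell_type"] == ct]
        for cutoff in design.fdr_cutoffs:
            sig = sub[sub["fdr"] < cutoff]
            rows.append({
                "cell_type": ct, "fdr_cutoff": cutoff,
                "n_tested": len(sub),
                "n_up": int((sig["log2fc"] > 0).sum()),
                "n_down": int((sig["log2fc"] < 0).sum()),
                "n_significant": int((sig["log2fc"] != 0).sum()),
            })
    return DEResult(table=table, priors=priors, summary=pd.DataFrame(rows))


def top_signature_genes(de: DEResult, ct: str, k: int = 50) -> list[str]:
    """The k genes with smallest unadjusted p; ties break by |t| descending,
    then gene id."""
    sub = de.for_cell_type(ct).copy()
    if len(sub) < k:
        warnings.warn(f"{ct}: only {len(sub)} tested genes (< k={k})")
    sub["abs_t"] = sub["t"].abs()
    sub = sub.sort_values(["p", "abs_t", "gene"],
                          ascending=[True, False, True], kind="mergesort")
    return sub["gene"].head(k).tolist()
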