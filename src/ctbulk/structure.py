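"""Signature clustering with bootstrap stability, and missing-tolerant PCA.

Patients are clustered on the per-cell-type differential-expression
signatures (top-k genes by p-value) using complete linkage on a
pairwise-complete scaled Euclidean distance

    d(i, j) = sqrt( (D / |S_ij|) * sum_{g in S_ij} (x_ig - x_jg)^2 )

where S_ij are the columns observed in both rows and D the total column
count — the scaling keeps distances comparable between pairs with
different overlap.  Cluster support is assessed by multiscale bootstrap:
columns are resampled at several relative sizes r, the per-node bootstrap
probability BP_r is recorded, and the approximately-unbiased value AU is
extrapolated from the signed-distance/curvature fit

    Phi^{-1}(1 - BP_r) ~ v*sqrt(r) + c/sqrt(r),    AU = 1 - Phi(v - c).

PCA of aggregated profiles uses NIPALS, which skips missing entries
naturally: each score/loading update sums over observed cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .containers import DEResult, PseudobulkTensor
from .diffexp import top_signature_genes

__all__ = [
    "Dendrogram",
    "signature_matrix",
    "hcluster",
    "two_group_separation",
    "bootstrap_stability",
    "PCAResult",
    "nipals_pca",
    "to_newick",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


@dataclass
class Dendrogram:
    """Agglomeration result.

    Leaves have ids 0..n-1; merge step s creates node ``n + s`` from the two
    listed children at the given height.  ``memberships`` maps every
    internal node id to the frozenset of leaf labels below it.  ``bp`` and
    ``au`` (percent, in [0, 100]) are attached by ``bootstrap_stability``.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    memberships: dict[int, frozenset[str]]
    bp: dict[int, float] = field(default_factory=dict)
    au: dict[int, float] = field(default_factory=dict)
    flagged: set[int] = field(default_factory=set)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


def signature_matrix(
    pb: PseudobulkTensor,
    de: DEResult,
    cell_types: list[str],
    k: int = 50,
) -> pd.DataFrame:
    """Patients x signature-genes matrix; columns are (cell type, gene)
    pairs from each cell type's top-k DE genes, values straight from the
    tensor with missing entries preserved."""
    if not cell_types:
        raise ValueError("empty signature: no cell types requested")
    blocks = []
    for ct in cell_types:
        genes = top_signature_genes(de, ct, k)
        if not genes:
            raise ValueError(f"empty signature for cell type {ct!r}")
        blk = pb.values[ct].loc[genes].T
        blk.columns = pd.MultiIndex.from_product([[ct], blk.columns],
                                                 names=["cell_type", "gene"])
        blocks.append(blk)
    return pd.concat(blocks, axis=1)


def _pairwise_complete_sq_euclidean(X: np.ndarray) -> np.ndarray:
    """Scaled squared Euclidean distances with per-pair complete columns."""
    obs = ~np.isnan(X)
    Xf = np.where(obs, X, 0.0)
    obs_f = obs.astype(float)
    shared = obs_f @ obs_f.T
    sq = Xf**2
    t1 = sq @ obs_f.T
    cross = Xf @ Xf.T
    sqd = t1 + t1.T - 2.0 * cross
    n, D = X.shape
    bad = (shared == 0) & ~np.eye(n, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"rows {i} and {j} share no observed columns")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = D / np.maximum(shared, 1.0) * np.maximum(sqd, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def hcluster(matrix: pd.DataFrame | np.ndarray,
             labels: list[str] | None = None) -> Dendrogram:
    """Complete-linkage agglomeration on the pairwise-complete scaled
    Euclidean distance; ties break toward the smaller node-id pair."""
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index) if labels is None else labels
        X = matrix.to_numpy(float)
    else:
        X = np.asarray(matrix, float)
        labels = [str(i) for i in range(X.shape[0])] if labels is None else labels
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    dist = np.sqrt(_pairwise_complete_sq_euclidean(X))

    # active cluster table: node id -> set of leaf indexes
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    memberships: dict[int, frozenset[str]] = {}
    next_id = n
    active = sorted(members)
    while len(active) > 1:
        best_pair, best_d = None, np.inf
        for ai in range(len(active)):
            for bj in range(ai + 1, len(active)):
                key = (active[ai], active[bj])
                dd = d[key]
                if dd < best_d:  # strict: first (smallest-id) pair wins ties
                    best_d, best_pair = dd, key
        i, j = best_pair
        members[next_id] = members.pop(i) | members.pop(j)
        active = [a for a in active if a not in (i, j)]
        for a in active:
            ka_i = (min(a, i), max(a, i))
            ka_j = (min(a, j), max(a, j))
            d[(a, next_id)] = max(d.pop(ka_i), d.pop(ka_j))
        d.pop((i, j))
        merges.append((i, j, float(best_d)))
        memberships[next_id] = frozenset(labels[x] for x in members[next_id])
        active.append(next_id)
        next_id += 1
    return Dendrogram(leaves=list(labels), merges=merges,
                      memberships=memberships)


def two_group_separation(dend: Dendrogram, groups: pd.Series) -> dict:
    """Cut the tree at the root into 2 clusters and compare with the group
    labels: exact-partition flag plus adjusted Rand index."""
    root = dend.n_leaves + len(dend.merges) - 1
    left_id, right_id, _ = dend.merges[-1]

    def leafset(node: int) -> frozenset:
        if node < dend.n_leaves:
            return frozenset([dend.leaves[node]])
        return dend.memberships[node]

    left = leafset(left_id)
    cluster_of = {leaf: (0 if leaf in left else 1) for leaf in dend.leaves}
    pred = [cluster_of[leaf] for leaf in dend.leaves]
    true = [groups[leaf] for leaf in dend.leaves]
    partition = {frozenset(l for l in dend.leaves if groups[l] == g)
                 for g in set(true)}
    perfect = {left, leafset(right_id)} == partition
    return {"perfect": bool(perfect),
            "ari": float(adjusted_rand_score(true, pred))}


def bootstrap_stability(
    matrix: pd.DataFrame,
    dend: Dendrogram,
    n_boot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
) -> Dendrogram:
    """Multiscale bootstrap support for every internal node.

    Columns are resampled with replacement to round(r * D) columns at each
    relative scale r; BP_r(node) is the fraction of replicates whose tree
    contains the node's exact leaf-membership set.  AU extrapolates the
    multiscale curve by a weighted probit fit; BP is reported at r = 1.
    Both are attached to (a copy of) the dendrogram in percent.
    """
    if list(matrix.index) != dend.leaves:
        raise ValueError("matrix rows and dendrogram leaves disagree")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; support values will be noisy")
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(float)
    D = X.shape[1]
    nodes = sorted(dend.memberships)
    counts = np.zeros((len(scales), len(nodes)))
    valid = np.zeros(len(scales))
    node_sets = [dend.memberships[nd] for nd in nodes]
    for si, r in enumerate(scales):
        m_r = max(2, int(round(r * D)))
        for _ in range(n_boot):
            cols = rng.integers(0, D, size=m_r)
            try:
                boot = hcluster(X[:, cols], labels=dend.leaves)
            except ValueError:
                continue
            got = set(boot.memberships.values())
            valid[si] += 1
            for ni, s in enumerate(node_sets):
                if s in got:
                    counts[si, ni] += 1

    one = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    bp_out, au_out, flagged = {}, {}, set()
    sqrt_r = np.sqrt(np.asarray(scales, float))
    for ni, nd in enumerate(nodes):
        B = np.maximum(valid, 1.0)
        bp = counts[:, ni] / B
        if (bp == 1.0).all() or (bp == 0.0).all():
            # the multiscale curve is flat at a boundary: no probit fit exists
            bp_out[nd] = 100.0 * float(bp[one])
            au_out[nd] = 100.0 * float(bp[0])
            flagged.add(nd)
            continue
        bp_clamped = np.clip(bp, 1.0 / (B + 1.0), B / (B + 1.0))
        z = stats.norm.ppf(1.0 - bp_clamped)
        w = B * stats.norm.pdf(z) ** 2 / (bp_clamped * (1.0 - bp_clamped))
        A = np.column_stack([sqrt_r, 1.0 / sqrt_r])
        Aw = A * w[:, None]
        try:
            coef = np.linalg.solve(A.T @ Aw, Aw.T @ z)
            v, c = float(coef[0]), float(coef[1])
            au = 100.0 * (1.0 - stats.norm.cdf(v - c))
        except np.linalg.LinAlgError:
            au = np.nan
            flagged.add(nd)
        bp_out[nd] = 100.0 * float(bp[one])
        au_out[nd] = au
    return Dendrogram(leaves=dend.leaves, merges=list(dend.merges),
                      memberships=dict(dend.memberships),
                      bp=bp_out, au=au_out, flagged=flagged)


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    converged: list[bool]
    explained_ss: list[float]


def nipals_pca(
    matrix: pd.DataFrame,
    n_components: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PCAResult:
    """Sequential NIPALS PCA skipping missing entries.

    Rows are samples, columns variables.  Columns are mean-centered over
    their observed values; every column must have at least one observation.
    Score/loading updates and the deflation use observed entries only.  The
    sign convention makes the first nonzero loading of each component
    positive.  Non-converging components are flagged and iteration stops.
    """
    X = matrix.to_numpy(float).copy()
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        bad = matrix.columns[~obs.any(axis=0)][0]
        raise ValueError(f"column {bad!r} has no observed values")
    col_means = np.nanmean(X, axis=0)
    X = np.where(obs, X - col_means, 0.0)  # missing as 0 contribution
    n_components = min(n_components, n - 1, m)

    scores = np.zeros((n, n_components))
    loadings = np.zeros((m, n_components))
    converged: list[bool] = []
    explained: list[float] = []
    obs_f = obs.astype(float)
    for comp in range(n_components):
        # start from the column with largest observed variance
        var = (X**2).sum(axis=0) / np.maximum(obs_f.sum(axis=0) - 1, 1)
        t = X[:, int(np.argmax(var))].copy()
        if not np.any(t):
            t = np.ones(n)
        ok = False
        for _ in range(max_iter):
            denom_p = (t**2) @ obs_f
            p = (t @ X) / np.maximum(denom_p, np.finfo(float).tiny)
            norm = np.linalg.norm(p)
            if norm == 0:
                break
            p /= norm
            denom_t = obs_f @ (p**2)
            t_new = (X @ p) / np.maximum(denom_t, np.finfo(float).tiny)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1.0):
                t = t_new
                ok = True
                break
            t = t_new
        nz = np.flatnonzero(p)
        if nz.size and p[nz[0]] < 0:
            p = -p
            t = -t
        scores[:, comp] = t
        loadings[:, comp] = p
        explained.append(float((np.outer(t, p)[obs] ** 2).sum()))
        converged.append(ok)
        X = X - np.where(obs, np.outer(t, p), 0.0)
        if not ok:
            warnings.warn(f"NIPALS component {comp + 1} stopped at max_iter "
                          "without reaching tol; flagged")
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns,
                              columns=comp_names),
        converged=converged,
        explained_ss=explained,
    )


def to_newick(dend: Dendrogram) -> str:
    """Newick serialization with AU/BP node comments (percent)."""
    heights = {dend.n_leaves + s: h for s, (_, _, h) in enumerate(dend.merges)}

    def render(node: int, parent_h: float) -> str:
        h = heights.get(node, 0.0)
        blen = max(parent_h - h, 0.0)
        if node < dend.n_leaves:
            return f"{dend.leaves[node]}:{blen:.6g}"
        step = node - dend.n_leaves
        i, j, _ = dend.merges[step]
        inner = f"({render(i, h)},{render(j, h)})"
        note = ""
        if node in dend.au or node in dend.bp:
            au = dend.au.get(node, float('nan'))
            bp = dend.bp.get(node, float('nan'))
            note = f"[&&AU={au:.1f},BP={bp:.1f}]"
        return f"{inner}{note}:{blen:.6g}"

    root = dend.n_leaves + len(dend.merges) - 1
    root_h = heights[root]
    i, j, _ = dend.merges[-1]
    au = dend.au.get(root)
    note = f"[&&AU={au:.1f},BP={dend.bp.get(root, float('nan')):.1f}]" \
        if au is not None else ""
    return f"({render(i, root_h)},{render(j, root_h)}){note};"
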