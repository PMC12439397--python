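"""Ranked-list (ordered-query) gene-set enrichment with a custom background.

For a gene list ranked by differential-expression p-value (sign ignored), a
set is tested against every prefix of the ranking: with background size N,
set size K (after intersecting with the background) and k_L set members in
the first L genes, the prefix score is the hypergeometric upper tail
P[X >= k_L | N, K, L], and the set's statistic is the minimum over L.  Only
prefixes ending right where a member enters the list (plus the full list)
need checking: at fixed overlap the tail probability only grows with L, so
no minimum is lost by skipping the in-between lengths.

Because the minimum over prefixes is not a p-value, significance is
calibrated family-wise by permutation: the ranking is shuffled, the minimum
min-p across all sets is recorded per shuffle (max-T style), and a set's
adjusted p is the (r+1)/(n+1) fraction of shuffles at or below its observed
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EnrichmentResult", "ordered_min_p", "calibrate_and_adjust"]

MIN_SET_SIZE = 3


@dataclass
class EnrichmentResult:
    set_name: str
    min_p: float
    best_prefix: int
    overlap_at_best: int
    set_size: int
    adjusted_p: float = np.nan


def ordered_min_p(
    ranked_genes: list[str],
    gene_set: set[str],
    background: set[str],
) -> tuple[float, int, int]:
    """Minimum hypergeometric tail over ranking prefixes.

    Returns (min_p, best prefix length L*, overlap at L*).  The ranked
    genes must be drawn from the background; the set is intersected with
    the background before testing.  An empty intersection scores p = 1 at
    the full-list prefix.
    """
    extra = set(ranked_genes) - background
    if extra:
        raise ValueError(
            f"{len(extra)} ranked gene(s) absent from background, e.g. "
            f"{sorted(extra)[:3]}"
        )
    N = len(background)
    members = gene_set & background
    K = len(members)
    L_full = len(ranked_genes)
    if K == 0:
        return 1.0, L_full, 0
    is_member = np.fromiter((g in members for g in ranked_genes), bool,
                            count=L_full)
    hits = np.flatnonzero(is_member) + 1  # 1-based prefix lengths
    return _min_p_from_positions(hits, K, N, L_full)


def _min_p_from_positions(
    hits: np.ndarray, K: int, N: int, L_full: int
) -> tuple[float, int, int]:
    """Fast reduced-grid minimum: prefixes ending at member entries plus the
    full list; k at the i-th member position is i+1."""
    n_in_list = len(hits)
    grid_L = np.append(hits, L_full)
    grid_k = np.append(np.arange(1, n_in_list + 1), n_in_list)
    p = stats.hypergeom.sf(grid_k - 1, N, K, grid_L)
    best = int(np.argmin(p))
    return float(p[best]), int(grid_L[best]), int(grid_k[best])


def calibrate_and_adjust(
    ranked_genes: list[str],
    sets: dict[str, set[str]],
    background: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = MIN_SET_SIZE,
    max_set_frac: float = 0.5,
) -> list[EnrichmentResult]:
    """Score every set and attach permutation-calibrated family-wise
    adjusted p-values.

    Sets smaller than ``min_set_size`` or larger than ``max_set_frac`` of
    the background (after intersection) are skipped.  Each permutation
    shuffles the ranking and records the minimum min-p across all kept
    sets; a set's adjusted p is the fraction of permutations whose family
    minimum is <= the set's observed min-p, with the (r+1)/(n+1)
    estimator.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; adjusted p-values will be "
                      "coarse")
    kept: dict[str, set[str]] = {}
    for name, s in sets.items():
        inter = s & background
        if len(inter) < min_set_size or len(inter) > max_set_frac * len(background):
            continue
        kept[name] = inter
    results = []
    for name, s in kept.items():
        p, L, k = ordered_min_p(ranked_genes, s, background)
        results.append(EnrichmentResult(name, p, L, k, len(s)))
    if not results:
        return results

    rng = np.random.default_rng(seed)
    L_full = len(ranked_genes)
    N = len(background)
    masks = {
        name: np.fromiter((g in s for g in ranked_genes), bool, count=L_full)
        for name, s in kept.items()
    }
    sizes = {name: len(s) for name, s in kept.items()}
    null_min = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(L_full)
        null_min[b] = min(
            _min_p_from_positions(np.flatnonzero(masks[name][perm]) + 1,
                                  sizes[name], N, L_full)[0]
            for name in kept
        )
    for res in results:
        r = int((null_min <= res.min_p).sum())
        res.adjusted_p = (r + 1) / (n_perm + 1)
    return results
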