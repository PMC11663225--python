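"""Program-level analysis of differential expression results.

Row-z-scored hierarchical clustering with fixed-k dendrogram cuts, the
rule extracting the double-treatment-high gene groups, and a weighted
Kolmogorov-Smirnov (GSEA) running enrichment score with gene-label
permutation significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

logger = logging.getLogger(__name__)

DOUBLE_TREATMENT = "TGFB1_MEKI"


@dataclass
class ZMatrix:
    """Row-z-scored genes x conditions matrix; constant rows become zeros."""

    values: pd.DataFrame
    constant_rows: list[str] = field(default_factory=list)


@dataclass
class GeneGroup:
    index: int
    members: list[str]
    condition_means: pd.Series


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    running: np.ndarray
    hit_indices: np.ndarray
    nes: float | None = None
    pvalue: float | None = None
    padj: float | None = None
    size: int = 0


def zscore_rows(matrix: pd.DataFrame) -> ZMatrix:
    """(x - row mean) / row sample SD (ddof=1); constant rows -> zeros."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to z-score rows")
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] <= 0
    sd[const] = 1.0
    z = (arr - mean) / sd
    z[const] = 0.0
    return ZMatrix(
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        constant_rows=list(matrix.index[const]),
    )


def cluster_and_cut(
    zmatrix: ZMatrix, k: int, method: str = "complete"
) -> list[GeneGroup]:
    """Agglomerative clustering (Euclidean) cut to exactly k groups.

    Groups are indexed by dendrogram leaf order (the order a heatmap
    would display them in).
    """
    values = zmatrix.values
    n = len(values)
    if k > n:
        raise ValueError("k exceeds the number of genes")
    if k < 1:
        raise ValueError("k must be positive")
    if method not in {"complete", "average", "ward"}:
        raise ValueError(f"unsupported linkage {method!r}")
    if n == 1:
        return [GeneGroup(0, list(values.index), values.iloc[0])]
    Z = linkage(values.to_numpy(), method=method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    leaf_order = leaves_list(Z)
    seen: list[int] = []
    for leaf in leaf_order:
        lab = labels[leaf]
        if lab not in seen:
            seen.append(lab)
    groups = []
    for gi, lab in enumerate(seen):
        members = list(values.index[labels == lab])
        means = values.loc[members].mean(axis=0)
        groups.append(GeneGroup(gi, members, means))
    return groups


def select_double_high_groups(
    groups: list[GeneGroup], double_condition: str = DOUBLE_TREATMENT
) -> set[str]:
    """Union of groups whose double-treatment mean z is the maximum across
    conditions and positive."""
    selected: set[str] = set()
    for g in groups:
        if double_condition not in g.condition_means.index:
            raise ValueError(f"no condition labelled {double_condition!r}")
        m = g.condition_means
        if m[double_condition] > 0 and m[double_condition] >= m.max():
            selected |= set(g.members)
    if not selected:
        logger.warning("no group has its maximum mean z in %s", double_condition)
    return selected


# ------------------------------------------------------------------ GSEA


def _running_sum(
    metric: np.ndarray, hit_mask: np.ndarray, weight: float
) -> np.ndarray:
    n = metric.size
    n_hit = int(hit_mask.sum())
    w = np.abs(metric) ** weight
    w_hit = np.where(hit_mask, w, 0.0)
    denom = w_hit.sum()
    if denom <= 0:  # all hit weights zero (e.g. p>0 and zero metrics)
        w_hit = hit_mask.astype(float)
        denom = w_hit.sum()
    steps = w_hit / denom
    if n_hit < n:
        steps = steps - (~hit_mask) / float(n - n_hit)
    return np.cumsum(steps)


def _extremum(running: np.ndarray) -> float:
    return float(running[np.argmax(np.abs(running))])


def gsea_score(
    ranked_genes: list[str],
    metric: np.ndarray,
    gene_set: set[str],
    weight: float = 1.0,
) -> EnrichmentResult:
    """Weighted-KS running enrichment score on a pre-ranked gene list.

    Hits add |metric|**weight normalised over hits; misses subtract
    1/(N - N_hit); the ES is the signed extremum of the running sum.
    """
    if len(set(ranked_genes)) != len(ranked_genes):
        raise ValueError("ranked gene list contains duplicates")
    metric = np.asarray(metric, dtype=float)
    if metric.size != len(ranked_genes):
        raise ValueError("metric length must match ranked list")
    hit_mask = np.fromiter(
        (g in gene_set for g in ranked_genes), dtype=bool, count=len(ranked_genes)
    )
    if not hit_mask.any():
        raise ValueError("gene set has no overlap with the ranked list")
    running = _running_sum(metric, hit_mask, weight)
    return EnrichmentResult(
        gene_set="",
        es=_extremum(running),
        running=running,
        hit_indices=np.flatnonzero(hit_mask),
        size=int(hit_mask.sum()),
    )


def _null_es(
    metric: np.ndarray, n_hit: int, weight: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES under gene-label permutation (random hit positions), vectorised."""
    n = metric.size
    w = np.abs(metric) ** weight
    miss = 1.0 / (n - n_hit) if n_hit < n else 0.0
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    idx = order[:, :n_hit]
    delta = np.full((n_perm, n), -miss)
    wh = w[idx]
    denom = wh.sum(axis=1, keepdims=True)
    denom = np.where(denom <= 0, n_hit, denom)
    wh = np.where(denom > 0, wh, 1.0)
    np.put_along_axis(delta, idx, wh / denom, axis=1)
    running = np.cumsum(delta, axis=1)
    pick = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), pick]


def gsea_permutation(
    ranked_genes: list[str],
    metric: np.ndarray,
    gene_set: set[str],
    n_perm: int = 999,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Add permutation NES and p to the running-score ES.

    p is two-sided on |ES| over the gene-label permutation null,
    p = (1 + #{|null| >= |ES|}) / (1 + n_perm); NES divides the ES by the
    mean |null ES| of the same sign (NA with a warning when no null ES
    shares the sign).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    res = gsea_score(ranked_genes, metric, gene_set, weight)
    rng = np.random.default_rng(seed)
    null = _null_es(np.asarray(metric, float), res.size, weight, n_perm, rng)
    res.pvalue = float((1 + np.sum(np.abs(null) >= abs(res.es))) / (1 + n_perm))
    same_sign = null[np.sign(null) == np.sign(res.es)]
    if same_sign.size == 0 or np.mean(np.abs(same_sign)) == 0:
        logger.warning("all permutation ES of opposite sign; NES undefined")
        res.nes = None
    else:
        res.nes = float(res.es / np.mean(np.abs(same_sign)))
    return res


def gsea(
    ranked_genes: list[str],
    metric: np.ndarray,
    gene_sets: dict[str, set[str]],
    n_perm: int = 999,
    seed: int = 0,
    weight: float = 1.0,
) -> dict[str, EnrichmentResult]:
    """Run permutation GSEA over several gene sets; BH-adjust across sets."""
    from .diffexpr import adjust_bh

    results: dict[str, EnrichmentResult] = {}
    for i, (name, gs) in enumerate(gene_sets.items()):
        res = gsea_permutation(ranked_genes, metric, gs, n_perm, seed + i, weight)
        res.gene_set = name
        results[name] = res
    padj = adjust_bh([results[n].pvalue for n in results])
    for name, q in zip(results, padj):
        results[name].padj = float(q)
    return results


def rank_by_lfc(
    de_table: pd.DataFrame, padj_threshold: float = 0.05
) -> tuple[list[str], np.ndarray]:
    """Ranking metric used by the enrichment stage: log2 fold changes of
    the significant genes (padj below threshold), sorted descending, ties
    broken by gene symbol for determinism."""
    sig = de_table[de_table["padj"] < padj_threshold].copy()
    sig = sig.sort_index().sort_values("log2fc", ascending=False, kind="mergesort")
    return list(sig.index), sig["log2fc"].to_numpy()
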