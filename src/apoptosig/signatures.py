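"""Treatment-specific gene signatures and cell-level module scores.

Signatures are the genes passing padj < 0.05 and log2FC > 1 in exactly
one treatment-vs-DMSO contrast.  The module score re-implements the
Seurat-style bin-matched control scheme: genes are binned by average
expression, each signature gene draws control genes from its own bin,
and a cell's score is the mean signature expression minus the mean
pooled control expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PADJ_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0


@dataclass
class GeneSignature:
    name: str
    members: set[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} is empty")


def derive_treatment_signatures(
    de_tables: dict[str, pd.DataFrame],
    padj_threshold: float = PADJ_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> dict[str, GeneSignature]:
    """Genes with padj < threshold AND log2fc > threshold in exactly one
    treatment become that treatment's signature (one-sided, up-regulated).

    Treatments whose unique set is empty are omitted from the result.
    """
    if len(de_tables) < 2:
        raise ValueError("need at least 2 treatments")
    passing: dict[str, set[str]] = {}
    for treatment, table in de_tables.items():
        if table.empty:
            raise ValueError(f"empty DE table for treatment {treatment!r}")
        mask = (table["padj"] < padj_threshold) & (table["log2fc"] > lfc_threshold)
        passing[treatment] = set(table.index[mask.fillna(False)])
    signatures: dict[str, GeneSignature] = {}
    for treatment, genes in passing.items():
        others = set().union(
            *[g for t, g in passing.items() if t != treatment]
        )
        unique = genes - others
        if unique:
            signatures[treatment] = GeneSignature(
                name=treatment,
                members=unique,
                provenance={g: f"unique:{treatment}" for g in unique},
            )
    # signatures are pairwise disjoint by construction; assert the invariant
    all_members: set[str] = set()
    for sig in signatures.values():
        assert not (all_members & sig.members), "treatment signatures overlap"
        all_members |= sig.members
    return signatures


def module_score(
    expr: pd.DataFrame,
    signature: GeneSignature | set[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Bin-matched module score per cell (``expr`` is cells x genes).

    Genes are ranked by average expression across cells (ties broken by
    symbol) and split into ``n_bins`` equal-size bins; each signature gene
    contributes ``n_ctrl`` control genes sampled from its bin (without
    replacement when the bin is large enough, with replacement otherwise).
    score(cell) = mean expression over signature genes minus mean
    expression over the pooled control draws.
    """
    members = signature.members if isinstance(signature, GeneSignature) else set(signature)
    genes = list(expr.columns)
    if len(genes) < n_bins:
        raise ValueError("fewer genes than bins")
    present = sorted(members & set(genes))
    if not present:
        raise ValueError("signature has no overlap with expressed genes")
    avg = expr.mean(axis=0)
    order = sorted(genes, key=lambda g: (avg[g], g))
    bin_of: dict[str, int] = {}
    bins: list[list[str]] = []
    for b, chunk in enumerate(np.array_split(np.array(order, dtype=object), n_bins)):
        bins.append(list(chunk))
        for g in chunk:
            bin_of[g] = b
    rng = np.random.default_rng(seed)
    ctrl: list[str] = []
    for g in present:
        pool = bins[bin_of[g]]
        replace = len(pool) < n_ctrl
        picked = rng.choice(np.array(pool, dtype=object), size=n_ctrl, replace=replace)
        ctrl.extend(picked.tolist())
    sig_mean = expr[present].mean(axis=1)
    ctrl_mean = expr[ctrl].mean(axis=1)
    score = sig_mean - ctrl_mean
    score.name = "module_score"
    return score


def score_by_state(scores: pd.Series, labels: pd.Series) -> tuple[pd.DataFrame, str, bool]:
    """Per-state summary (mean, median, sd, n) and the argmax state by mean.

    Ties are broken lexicographically and flagged.
    """
    if not scores.index.equals(labels.index):
        labels = labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("every cell must have a state label")
    df = pd.DataFrame({"score": scores, "state": labels})
    summary = (
        df.groupby("state")["score"]
        .agg(mean="mean", median="median", sd="std", n="size")
        .sort_index()
    )
    best = summary["mean"].max()
    winners = sorted(summary.index[summary["mean"] == best])
    return summary, winners[0], len(winners) > 1


def signatures_to_gmt(signatures: dict[str, GeneSignature]) -> dict[str, list[str]]:
    return {name: sorted(sig.members) for name, sig in signatures.items()}
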