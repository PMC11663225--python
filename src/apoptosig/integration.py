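"""Set-algebra core assembling the context-specific apoptosis signature.

The signature is built from four gene sets — the double-treatment DEG
groups of the two cell lines, the genes uniquely bound (SMAD4 peaks) in
the double-treatment condition, and a pro-apoptotic GO-derived universe —
by taking four specific regions of their Venn partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import GeneSignature

logger = logging.getLogger(__name__)


def normalize_symbols(symbols) -> set[str]:
    return {str(s).strip().upper() for s in symbols if str(s).strip()}


@dataclass
class GeneUniverse:
    name: str
    members: set[str]
    note: str = ""


def build_apoptosis_universe(
    apoptosis_set,
    neg_reg_set,
    ortholog_map: dict[str, list[str]] | None = None,
) -> GeneUniverse:
    """Pro-apoptotic universe: apoptosis genes minus negative regulators.

    An optional ortholog map (e.g. mouse -> human, one-to-many allowed)
    translates both inputs first; unmapped symbols are dropped with a
    logged count.
    """
    if not apoptosis_set or not neg_reg_set:
        raise ValueError("both input sets must be nonempty")

    def _map(genes) -> set[str]:
        genes = normalize_symbols(genes)
        if ortholog_map is None:
            return genes
        mapped: set[str] = set()
        dropped = 0
        for g in genes:
            targets = ortholog_map.get(g)
            if targets:
                mapped |= normalize_symbols(
                    targets if isinstance(targets, (list, tuple, set)) else [targets]
                )
            else:
                dropped += 1
        if dropped:
            logger.info("ortholog map dropped %d unmapped symbols", dropped)
        return mapped

    members = _map(apoptosis_set) - _map(neg_reg_set)
    if not members:
        logger.warning("apoptosis universe is empty after subtraction")
    return GeneUniverse(
        "pro_apoptotic",
        members,
        note="apoptotic-process set minus negative-regulation set",
    )


def build_invasiveness_universe(axl_set, hoek_set, verfaillie_set) -> GeneUniverse:
    """Union of the three published invasive programs."""
    sets = [normalize_symbols(s) for s in (axl_set, hoek_set, verfaillie_set)]
    if not any(sets):
        raise ValueError("all invasiveness inputs are empty")
    return GeneUniverse(
        "pro_invasive", set().union(*sets), note="AXL + Hoek + Verfaillie union"
    )


@dataclass
class VennPartition:
    set_names: list[str]
    patterns: dict[str, set[str]]  # bit-pattern (e.g. "1011") -> genes

    def counts(self) -> dict[str, int]:
        return {p: len(g) for p, g in self.patterns.items()}

    def pattern_for(self, include: set[str]) -> str:
        return "".join("1" if n in include else "0" for n in self.set_names)


def venn_partition(named_sets: dict[str, set]) -> VennPartition:
    """All 2**n - 1 exclusive membership patterns of 2-5 named sets."""
    n = len(named_sets)
    if not 2 <= n <= 5:
        raise ValueError("venn partition supports 2-5 sets")
    names = list(named_sets)
    sets = {k: normalize_symbols(v) for k, v in named_sets.items()}
    patterns: dict[str, set[str]] = {}
    for r in range(1, n + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*[sets[c] for c in combo])
            outside = set().union(*[sets[c] for c in names if c not in combo]) if r < n else set()
            key = "".join("1" if name in combo else "0" for name in names)
            patterns[key] = inside - outside
    # invariants: disjoint patterns covering the union of the inputs
    union_all = set().union(*sets.values())
    covered: set[str] = set()
    for key, genes in patterns.items():
        assert not (covered & genes), "venn patterns overlap"
        covered |= genes
    assert covered == union_all, "venn patterns do not cover the input union"
    return VennPartition(names, patterns)


#: canonical role names for the apoptosis-signature Venn
SIGNATURE_ROLES = ("deg_line_a", "deg_line_b", "peak_genes", "apoptosis_universe")

#: the four Venn regions whose union forms the signature, expressed as the
#: roles included in each exclusive pattern
SIGNATURE_PATTERNS = (
    {"deg_line_a", "deg_line_b", "peak_genes", "apoptosis_universe"},  # core
    {"deg_line_b", "peak_genes", "apoptosis_universe"},
    {"deg_line_a", "peak_genes", "apoptosis_universe"},
    {"deg_line_a", "deg_line_b", "apoptosis_universe"},
)


def assemble_apoptosis_signature(partition: VennPartition) -> GeneSignature | None:
    """Union of the four Venn regions of interest, with per-gene provenance.

    The partition must be built from exactly the four role-named sets in
    ``SIGNATURE_ROLES``.  The selected regions are exclusive patterns: a
    gene in e.g. the line-B/peaks/universe region is by construction not a
    line-A DEG.
    """
    if set(partition.set_names) != set(SIGNATURE_ROLES):
        raise ValueError(f"partition must be over the sets {SIGNATURE_ROLES}")
    members: set[str] = set()
    provenance: dict[str, str] = {}
    for include in SIGNATURE_PATTERNS:
        key = partition.pattern_for(include)
        tag = "&".join(sorted(include))
        for gene in partition.patterns.get(key, set()):
            members.add(gene)
            provenance[gene] = tag
    if not members:
        logger.warning("assembled apoptosis signature is empty")
        return None
    return GeneSignature("apoptosis_signature", members, provenance)


def baseline_marker_screen(
    expr: pd.DataFrame,
    groups: pd.Series,
    lfc_thresh: float = 0.3,
    p_thresh: float = 0.05,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Baseline expression screen between sensitive and resistant lines.

    ``expr`` is genes x cell lines (FPKM-like); ``groups`` maps cell line
    to "sensitive" / "resistant".  Fold change is the difference of
    log2(x+1) group means (sensitive minus resistant); p is a two-sided
    Welch t-test.  A gene is flagged when |lfc| > lfc_thresh strictly and
    p < p_thresh.
    """
    labels = groups.reindex(expr.columns)
    sens = expr.columns[labels == "sensitive"]
    res = expr.columns[labels == "resistant"]
    if len(sens) < 2 or len(res) < 2:
        raise ValueError("each group needs >=2 cell lines")
    mat = np.log2(expr.to_numpy(dtype=float) + 1.0) if log_transform else expr.to_numpy(float)
    mat = pd.DataFrame(mat, index=expr.index, columns=expr.columns)
    ms = mat[sens].mean(axis=1)
    mr = mat[res].mean(axis=1)
    lfc = ms - mr
    t, p = stats.ttest_ind(mat[sens], mat[res], axis=1, equal_var=False)
    flagged = (np.abs(lfc) > lfc_thresh) & (p < p_thresh)
    direction = np.where(
        ~flagged, "ns", np.where(lfc > 0, "up_in_sensitive", "up_in_resistant")
    )
    return pd.DataFrame(
        {"lfc": lfc, "pvalue": p, "flagged": flagged, "direction": direction},
        index=expr.index,
    )
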