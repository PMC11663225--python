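"""CUT&RUN peak interval operations.

All coordinates are 0-based half-open throughout (BED native).  The
replicate consensus is the base-pair intersection of the two antibody
replicates; condition-unique regions come from a maximal partition of the
genome by membership pattern; peak-to-gene association uses GREAT-style
"basal plus extension" regulatory domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class PeakSet:
    """Strand-less genomic intervals with optional scores."""

    intervals: pd.DataFrame  # columns chrom, start, end [, name, score]

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"peak table lacks column {col!r}")
        if len(df):
            if (df["start"].to_numpy() < 0).any():
                raise ValueError("negative coordinate")
            if (df["start"].to_numpy() >= df["end"].to_numpy()).any():
                raise ValueError("interval with start >= end")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.intervals.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )

    def merged(self) -> "PeakSet":
        """Union of the intervals as disjoint sorted intervals."""
        rows = []
        for chrom, sub in self.sorted().intervals.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(sub["start"], sub["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e))
        return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def total_bases(self) -> int:
        m = self.merged().intervals
        return int((m["end"] - m["start"]).sum()) if len(m) else 0

    def filter_min_width(self, min_width: int) -> "PeakSet":
        """Drop intervals narrower than ``min_width`` (e.g. the few-bp edge
        slivers a base-pair membership partition produces around jittered
        replicate boundaries)."""
        df = self.intervals
        keep = (df["end"] - df["start"]) >= min_width
        return PeakSet(df[keep].reset_index(drop=True))


def from_records(records) -> PeakSet:
    return PeakSet(pd.DataFrame(records, columns=["chrom", "start", "end"]))


# ------------------------------------------------------------------ BED


def read_bed(path) -> PeakSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer coordinate at line {lineno}") from exc
            if start < 0:
                raise ValueError(f"{path}: negative coordinate at line {lineno}")
            if start >= end:
                raise ValueError(f"{path}: start >= end at line {lineno}")
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            rows.append((fields[0], start, end, name, score))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]))


def write_bed(peaks: PeakSet, path) -> None:
    df = peaks.intervals
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            name = getattr(row, "name", None) or f"peak_{i + 1}"
            score = getattr(row, "score", 0.0) or 0.0
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{name}\t{score:g}\t.\n"
            )


# ------------------------------------------------------------ consensus


def reproducible_peaks(rep_a: PeakSet, rep_b: PeakSet) -> PeakSet:
    """Base-pair intersection of two replicate peak sets (disjoint output)."""
    a = rep_a.merged().intervals
    b = rep_b.merged().intervals
    rows = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        ia = a[a["chrom"] == chrom].to_numpy()
        ib = b[b["chrom"] == chrom].to_numpy()
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][1], ib[j][1])
            e = min(ia[i][2], ib[j][2])
            if s < e:
                rows.append((chrom, int(s), int(e)))
            if ia[i][2] < ib[j][2]:
                i += 1
            else:
                j += 1
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@dataclass
class MembershipPartition:
    """Maximal genome regions of constant membership across named peak sets."""

    set_names: list[str]
    regions: pd.DataFrame  # chrom, start, end, pattern (e.g. "101")
    counts: dict[str, int] = field(default_factory=dict)

    def unique_sets(self) -> dict[str, PeakSet]:
        out = {}
        for i, name in enumerate(self.set_names):
            pattern = "".join("1" if j == i else "0" for j in range(len(self.set_names)))
            sub = self.regions[self.regions["pattern"] == pattern]
            out[name] = PeakSet(sub[["chrom", "start", "end"]].copy())
        return out


def multiway_membership(named_sets: dict[str, "PeakSet"]) -> MembershipPartition:
    """Partition the union of the inputs by membership bit-pattern."""
    if len(named_sets) < 2:
        raise ValueError("need at least two named peak sets")
    names = list(named_sets)
    merged = {n: named_sets[n].merged().intervals for n in names}
    chroms = sorted(set().union(*[set(m["chrom"]) for m in merged.values()]))
    rows = []
    for chrom in chroms:
        bounds = set()
        per_set = {}
        for n in names:
            sub = merged[n][merged[n]["chrom"] == chrom]
            arr = sub[["start", "end"]].to_numpy()
            per_set[n] = arr
            bounds.update(arr.flatten().tolist())
        bounds = sorted(bounds)
        prev_pattern = None
        seg_start = None
        for s, e in zip(bounds[:-1], bounds[1:]):
            mid = (s + e) / 2
            pattern = "".join(
                "1"
                if any(a_s <= mid < a_e for a_s, a_e in per_set[n])
                else "0"
                for n in names
            )
            if pattern == "0" * len(names):
                if prev_pattern is not None:
                    rows.append((chrom, seg_start, s, prev_pattern))
                    prev_pattern = None
                continue
            if pattern == prev_pattern:
                continue  # segments between consecutive bounds are contiguous
            if prev_pattern is not None:
                rows.append((chrom, seg_start, s, prev_pattern))
            prev_pattern, seg_start = pattern, s
        if prev_pattern is not None:
            rows.append((chrom, seg_start, bounds[-1], prev_pattern))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "pattern"])
    counts = regions["pattern"].value_counts().to_dict() if len(regions) else {}
    return MembershipPartition(names, regions, counts)


# ----------------------------------------------------------- annotation


def _exon_list(row) -> list[tuple[int, int]]:
    starts = getattr(row, "exon_starts", None)
    ends = getattr(row, "exon_ends", None)
    if starts is None or ends is None or pd.isna(starts) or pd.isna(ends):
        return []
    ss = [int(v) for v in str(starts).split(",") if v != ""]
    ee = [int(v) for v in str(ends).split(",") if v != ""]
    return list(zip(ss, ee))


def annotate_peak(
    peak: tuple[str, int, int],
    annotation: pd.DataFrame,
    promoter_window: int = 1000,
) -> str:
    """Category of the peak midpoint: promoter-TSS > exonic > intronic > intergenic."""
    chrom, start, end = peak
    mid = (start + end) // 2
    genes = annotation[annotation["chrom"] == chrom]
    if genes.empty:
        return "intergenic"
    tss = genes["tss"].to_numpy()
    if (np.abs(mid - tss) <= promoter_window).any():
        return "promoter-TSS"
    in_body = genes[(genes["start"] <= mid) & (mid < genes["end"])]
    if in_body.empty:
        return "intergenic"
    for row in in_body.itertuples(index=False):
        for es, ee in _exon_list(row):
            if es <= mid < ee:
                return "exonic"
    return "intronic"


def annotate_peaks(peaks: PeakSet, annotation: pd.DataFrame, promoter_window: int = 1000) -> pd.Series:
    cats = [
        annotate_peak((r.chrom, int(r.start), int(r.end)), annotation, promoter_window)
        for r in peaks.intervals.itertuples(index=False)
    ]
    return pd.Series(cats, name="category")


# ---------------------------------------------------- regulatory domains


def regulatory_domains(
    annotation: pd.DataFrame,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """GREAT-style basal-plus-extension regulatory domain per gene.

    The basal domain is TSS-basal_up..TSS+basal_down (strand-oriented);
    the extension grows each side up to ``max_extension`` but stops at the
    nearest neighbouring gene's basal domain, clipped to chromosome bounds.
    Returns a DataFrame with symbol, chrom, basal_start/end, ext_start/end.
    """
    rows = []
    for chrom, sub in annotation.groupby("chrom", sort=True):
        sub = sub.sort_values("tss").reset_index(drop=True)
        basal = []
        for r in sub.itertuples(index=False):
            if r.strand == "+":
                b = (max(0, r.tss - basal_up), r.tss + basal_down)
            else:
                b = (max(0, r.tss - basal_down), r.tss + basal_up)
            basal.append(b)
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        for i, r in enumerate(sub.itertuples(index=False)):
            bs, be = basal[i]
            left_lim = 0
            for j in range(len(sub)):
                if j == i:
                    continue
                ob_s, ob_e = basal[j]
                if ob_e <= bs:
                    left_lim = max(left_lim, ob_e)
            right_lim = size if size is not None else None
            for j in range(len(sub)):
                if j == i:
                    continue
                ob_s, ob_e = basal[j]
                if ob_s >= be:
                    right_lim = ob_s if right_lim is None else min(right_lim, ob_s)
            es = max(bs - max_extension, left_lim)
            es = min(es, bs)
            ee = be + max_extension
            if right_lim is not None:
                ee = min(ee, max(right_lim, be))
            if size is not None:
                ee = min(ee, size)
                be_c = min(be, size)
            else:
                be_c = be
            rows.append((r.symbol, chrom, bs, be_c, max(0, es), max(ee, be_c)))
    return pd.DataFrame(
        rows,
        columns=["symbol", "chrom", "basal_start", "basal_end", "ext_start", "ext_end"],
    )


def peaks_to_genes(
    peaks: PeakSet, domains: pd.DataFrame
) -> tuple[set[str], dict[str, list[int]], list[int]]:
    """Associate peaks to genes whose extended domain they overlap by >=1 bp.

    Returns (gene set, per-gene supporting peak row indices, unassigned rows).
    """
    trees: dict[str, IntervalTree] = {}
    for r in domains.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.ext_start, r.ext_end, r.symbol)
    genes: set[str] = set()
    support: dict[str, list[int]] = {}
    unassigned: list[int] = []
    for idx, r in enumerate(peaks.intervals.itertuples(index=False)):
        tree = trees.get(r.chrom)
        hits = tree.overlap(int(r.start), int(r.end)) if tree else ()
        if not hits:
            unassigned.append(idx)
            continue
        for h in hits:
            genes.add(h.data)
            support.setdefault(h.data, []).append(idx)
    return genes, support, unassigned


# ------------------------------------------------------- signal profile


def scaled_signal_profile(
    coverage: dict[str, np.ndarray],
    peaks: PeakSet,
    n_bins_body: int = 50,
    flank_multiple: int = 2,
) -> np.ndarray:
    """Length-scaled signal matrix: each peak body -> ``n_bins_body`` bins,
    flanks of ``flank_multiple`` x width each side binned at the same
    percent resolution.  Out-of-chromosome flank bases are zero-padded.
    """
    n_flank_bins = n_bins_body * flank_multiple
    total_bins = n_bins_body + 2 * n_flank_bins
    out = np.zeros((len(peaks), total_bins))
    for i, r in enumerate(peaks.intervals.itertuples(index=False)):
        cov = coverage.get(r.chrom)
        width = int(r.end) - int(r.start)
        flank = flank_multiple * width
        seg_start = int(r.start) - flank
        seg_len = width + 2 * flank
        vals = np.zeros(seg_len)
        if cov is not None:
            lo = max(seg_start, 0)
            hi = min(seg_start + seg_len, len(cov))
            if hi > lo:
                vals[lo - seg_start : hi - seg_start] = cov[lo:hi]
        # per-base bin assignment at uniform percent resolution
        pos = np.arange(seg_len)
        bins = np.minimum((pos * total_bins) // seg_len, total_bins - 1)
        sums = np.bincount(bins, weights=vals, minlength=total_bins)
        cnts = np.bincount(bins, minlength=total_bins)
        out[i] = sums / np.maximum(cnts, 1)
    return out
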