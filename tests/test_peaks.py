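"""Interval operations: BED I/O, consensus, partition, annotation, domains,
peak-to-gene association and scaled profiles — each against per-base or
hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from apoptosig.peaks import (
    PeakSet,
    annotate_peak,
    annotate_peaks,
    multiway_membership,
    peaks_to_genes,
    read_bed,
    regulatory_domains,
    reproducible_peaks,
    scaled_signal_profile,
    write_bed,
)

TOY_CHROM_LEN = 10_000


def _random_peakset(rng, n=50, chrom="chr1", max_len=TOY_CHROM_LEN):
    starts = rng.integers(0, max_len - 100, size=n)
    lengths = rng.integers(1, 100, size=n)
    return PeakSet(
        pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": np.minimum(starts + lengths, max_len)}
        )
    )


def _base_mask(ps: PeakSet, chrom="chr1", length=TOY_CHROM_LEN):
    mask = np.zeros(length, dtype=bool)
    for r in ps.intervals.itertuples(index=False):
        if r.chrom == chrom:
            mask[r.start : r.end] = True
    return mask


# ------------------------------------------------------------------- BED


def test_bed_parse_simple(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t10\t20\n")
    ps = read_bed(p)
    row = ps.intervals.iloc[0]
    assert (row["chrom"], row["start"], row["end"]) == ("chr1", 10, 20)


def test_bed_round_trip(tmp_path, rng):
    ps = _random_peakset(rng, 30)
    path = tmp_path / "rt.bed"
    write_bed(ps, path)
    back = read_bed(path)
    pd.testing.assert_frame_equal(
        back.intervals[["chrom", "start", "end"]],
        ps.intervals[["chrom", "start", "end"]],
    )


@pytest.mark.parametrize(
    "content,msg",
    [
        ("chr1\t20\t10\n", "start >= end"),
        ("chr1\t-5\t10\n", "negative"),
        ("chr1\tx\t10\n", "non-integer"),
        ("chr1\t5\n", "malformed"),
    ],
)
def test_bed_malformed_lines_report_line_number(tmp_path, content, msg):
    p = tmp_path / "bad.bed"
    p.write_text(content)
    with pytest.raises(ValueError, match="line 1"):
        read_bed(p)


def test_peakset_rejects_inverted_interval():
    with pytest.raises(ValueError):
        PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [20], "end": [10]}))


# -------------------------------------------------------------- consensus


def test_consensus_hand_example():
    a = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]}))
    b = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [250]}))
    out = reproducible_peaks(a, b).intervals
    assert out.to_records(index=False).tolist() == [("chr1", 150, 200)]


def test_consensus_disjoint_inputs_empty():
    a = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}))
    b = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [60]}))
    assert len(reproducible_peaks(a, b)) == 0


def test_consensus_matches_per_base_oracle(rng):
    for _ in range(20):
        a, b = _random_peakset(rng), _random_peakset(rng)
        cons = reproducible_peaks(a, b)
        assert np.array_equal(_base_mask(cons), _base_mask(a) & _base_mask(b))
        # inclusion in both inputs
        assert not (_base_mask(cons) & ~_base_mask(a)).any()


# -------------------------------------------------------------- multi-way


def test_multiway_identical_sets_have_no_unique_regions(rng):
    a = _random_peakset(rng).merged()
    part = multiway_membership({"x": a, "y": a})
    uniq = part.unique_sets()
    assert len(uniq["x"]) == 0 and len(uniq["y"]) == 0
    shared = part.regions[part.regions["pattern"] == "11"]
    assert int((shared["end"] - shared["start"]).sum()) == a.total_bases()


def test_multiway_hand_example():
    a = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}))
    b = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [5], "end": [15]}))
    part = multiway_membership({"A": a, "B": b})
    got = {
        (r.start, r.end): r.pattern for r in part.regions.itertuples(index=False)
    }
    assert got == {(0, 5): "10", (5, 10): "11", (10, 15): "01"}


def test_multiway_matches_per_base_oracle(rng):
    for _ in range(10):
        sets = {f"s{i}": _random_peakset(rng, 25) for i in range(4)}
        part = multiway_membership(sets)
        masks = {n: _base_mask(ps) for n, ps in sets.items()}
        expected = np.zeros(TOY_CHROM_LEN, dtype=object)
        for pos in range(TOY_CHROM_LEN):
            expected[pos] = "".join("1" if masks[n][pos] else "0" for n in sets)
        got = np.full(TOY_CHROM_LEN, "0000", dtype=object)
        for r in part.regions.itertuples(index=False):
            got[r.start : r.end] = r.pattern
        assert np.array_equal(got, expected)
        # disjoint regions covering the union
        spans = part.regions.sort_values("start")
        overlaps = (spans["start"].to_numpy()[1:] < spans["end"].to_numpy()[:-1])
        assert not overlaps.any()


# -------------------------------------------------------------- annotation


@pytest.fixture(scope="module")
def toy_annotation():
    return pd.DataFrame(
        {
            "symbol": ["GA", "GB"],
            "chrom": ["chr1", "chr1"],
            "tss": [5000, 40_000],
            "strand": ["+", "-"],
            "start": [5000, 30_000],
            "end": [15_000, 40_000],
            "exon_starts": ["5000,14000", "30000,39500"],
            "exon_ends": ["5600,15000", "30400,40000"],
        }
    )


def test_annotate_promoter_priority(toy_annotation):
    # 100 bp upstream of GA's TSS
    assert annotate_peak(("chr1", 4850, 4950), toy_annotation) == "promoter-TSS"


def test_annotate_intronic(toy_annotation):
    assert annotate_peak(("chr1", 8000, 8200), toy_annotation) == "intronic"


def test_annotate_exonic(toy_annotation):
    assert annotate_peak(("chr1", 14_200, 14_400), toy_annotation) == "exonic"


def test_annotate_intergenic_and_missing_chrom(toy_annotation):
    assert annotate_peak(("chr1", 20_000, 20_100), toy_annotation) == "intergenic"
    assert annotate_peak(("chr9", 100, 200), toy_annotation) == "intergenic"


def test_annotate_matches_midpoint_oracle(rng, small_annotation):
    peaks = _random_peakset(rng, 200, chrom="chr1", max_len=2_000_000)
    cats = annotate_peaks(peaks, small_annotation, promoter_window=1000)

    def oracle(mid):
        sub = small_annotation[small_annotation["chrom"] == "chr1"]
        if (np.abs(sub["tss"] - mid) <= 1000).any():
            return "promoter-TSS"
        body = sub[(sub["start"] <= mid) & (mid < sub["end"])]
        if body.empty:
            return "intergenic"
        for r in body.itertuples(index=False):
            exs = [int(v) for v in r.exon_starts.split(",")]
            exe = [int(v) for v in r.exon_ends.split(",")]
            if any(s <= mid < e for s, e in zip(exs, exe)):
                return "exonic"
        return "intronic"

    expected = [
        oracle((r.start + r.end) // 2) for r in peaks.intervals.itertuples(index=False)
    ]
    assert list(cats) == expected
    assert set(cats) <= {"promoter-TSS", "exonic", "intronic", "intergenic"}


# ------------------------------------------------------------------ GREAT


def test_domains_single_gene_hand_example():
    ann = pd.DataFrame(
        {
            "symbol": ["G"],
            "chrom": ["chr1"],
            "tss": [10_000],
            "strand": ["+"],
            "start": [10_000],
            "end": [12_000],
        }
    )
    dom = regulatory_domains(
        ann, basal_up=5000, basal_down=1000, max_extension=1_000_000,
        chrom_sizes={"chr1": 2_000_000},
    ).iloc[0]
    assert (dom["basal_start"], dom["basal_end"]) == (5000, 11_000)
    assert (dom["ext_start"], dom["ext_end"]) == (0, 1_011_000)


def test_domains_stop_at_neighbouring_basal():
    ann = pd.DataFrame(
        {
            "symbol": ["L", "R"],
            "chrom": ["chr1", "chr1"],
            "tss": [50_000, 80_000],
            "strand": ["+", "+"],
            "start": [50_000, 80_000],
            "end": [52_000, 82_000],
        }
    )
    dom = regulatory_domains(ann, 5000, 1000, 1_000_000).set_index("symbol")
    # L basal [45000,51000), R basal [75000,81000)
    assert dom.loc["L", "ext_end"] == 75_000
    assert dom.loc["R", "ext_start"] == 51_000


def test_domains_basal_contained_and_order_invariant(small_annotation):
    dom = regulatory_domains(small_annotation)
    assert (dom["ext_start"] <= dom["basal_start"]).all()
    assert (dom["basal_end"] <= dom["ext_end"]).all()
    shuffled = small_annotation.sample(frac=1.0, random_state=1)
    dom2 = regulatory_domains(shuffled).sort_values("symbol").reset_index(drop=True)
    pd.testing.assert_frame_equal(dom.sort_values("symbol").reset_index(drop=True), dom2)


def test_peaks_to_genes_hand_and_oracle(rng, small_annotation):
    domains = regulatory_domains(small_annotation)
    peaks = _random_peakset(rng, 100, chrom="chr2", max_len=3_000_000)
    genes, support, unassigned = peaks_to_genes(peaks, domains)
    # brute-force pairwise overlap oracle
    expected = set()
    for r in peaks.intervals.itertuples(index=False):
        for d in domains.itertuples(index=False):
            if d.chrom == r.chrom and r.start < d.ext_end and d.ext_start < r.end:
                expected.add(d.symbol)
    assert genes == expected
    assert len(unassigned) + sum(1 for _ in support) >= 0  # structure sanity


def test_peak_overlapping_two_domains_maps_to_both():
    ann = pd.DataFrame(
        {
            "symbol": ["L", "R"],
            "chrom": ["chr1", "chr1"],
            "tss": [50_000, 60_000],
            "strand": ["+", "+"],
            "start": [50_000, 60_000],
            "end": [52_000, 62_000],
        }
    )
    domains = regulatory_domains(ann, 5000, 1000, 1_000_000)
    peaks = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [52_000], "end": [56_000]}))
    genes, _, _ = peaks_to_genes(peaks, domains)
    assert genes == {"L", "R"}


# ---------------------------------------------------------------- profile


def test_profile_uniform_coverage():
    cov = {"chr1": np.ones(5000)}
    peaks = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [2400]}))
    prof = scaled_signal_profile(cov, peaks, n_bins_body=10, flank_multiple=2)
    assert prof.shape == (1, 50)
    assert np.allclose(prof, 1.0)


def test_profile_body_indicator():
    cov = {"chr1": np.zeros(5000)}
    cov["chr1"][2000:2400] = 1.0
    peaks = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [2400]}))
    prof = scaled_signal_profile(cov, peaks, n_bins_body=10, flank_multiple=2)[0]
    assert np.allclose(prof[20:30], 1.0)
    assert np.allclose(prof[:20], 0.0) and np.allclose(prof[30:], 0.0)


def test_profile_matches_mean_pool_oracle(rng):
    cov = {"chr1": rng.uniform(size=8000)}
    start, end = 3000, 3173  # width not divisible by bins
    peaks = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]}))
    n_body, fm = 7, 2
    prof = scaled_signal_profile(cov, peaks, n_bins_body=n_body, flank_multiple=fm)[0]
    width = end - start
    seg = cov["chr1"][start - fm * width : end + fm * width]
    total_bins = n_body * (1 + 2 * fm)
    expected = np.zeros(total_bins)
    assign = (np.arange(seg.size) * total_bins) // seg.size
    for b in range(total_bins):
        expected[b] = seg[assign == b].mean()
    assert np.allclose(prof, expected)


def test_profile_zero_pads_outside_chromosome():
    cov = {"chr1": np.ones(1000)}
    peaks = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [300]}))
    prof = scaled_signal_profile(cov, peaks, n_bins_body=10, flank_multiple=2)[0]
    # left flank extends to -300; its first bins average in zero padding
    assert prof[0] < 1.0
    assert np.allclose(prof[20:30], 1.0)
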