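"""The fixture generators: determinism, calibration and round-trips."""

import numpy as np
import pandas as pd
import pytest

from apoptosig import io as asio, synthetic
from apoptosig.peaks import read_bed, reproducible_peaks
from apoptosig.synthetic import (
    PWM_COUNTS,
    TruthSpec,
    default_truth,
    make_annotation,
    simulate_counts,
    simulate_dose_response,
    simulate_peak_sequences,
    simulate_peaks,
    simulate_single_cell,
    write_fixture_bundle,
)


def null_truth(n=300, seed=0, **overrides) -> TruthSpec:
    genes = [f"G{i:05d}" for i in range(n)]
    kwargs = dict(gene_blocks={"null": genes}, effect_sizes={}, seed=seed)
    kwargs.update(overrides)
    return TruthSpec(**kwargs)


# ------------------------------------------------------------- truth spec


def test_truth_rejects_overlapping_blocks():
    with pytest.raises(ValueError, match="overlap"):
        TruthSpec(gene_blocks={"a": ["G1"], "b": ["G1"]}, effect_sizes={})


@pytest.mark.parametrize("frac", [-0.1, 1.2])
def test_truth_rejects_bad_fractions(frac):
    with pytest.raises(ValueError):
        TruthSpec(gene_blocks={"a": ["G1"]}, effect_sizes={}, reproducible_fraction=frac)


def test_truth_json_round_trip(tmp_path):
    truth = default_truth(n_genes=300, block_size=20, seed=3)
    asio.write_json({"truth_spec": truth.to_dict()}, tmp_path / "t.json")
    back = synthetic.read_truth(tmp_path / "t.json")
    assert back == truth


# ------------------------------------------------------------- annotation


def test_annotation_minimal_two_genes():
    ann = make_annotation(2, 1, seed=7)
    assert len(ann) == 2
    assert set(ann["chrom"]) == {"chr1"}
    assert ann["tss"].nunique() == 2
    assert set(ann["strand"]) <= {"+", "-"}


def test_annotation_deterministic():
    a = make_annotation(50, 2, seed=7)
    b = make_annotation(50, 2, seed=7)
    pd.testing.assert_frame_equal(a, b)


def test_annotation_chromosome_counts_sum():
    ann = make_annotation(500, 3, seed=1)
    assert ann.groupby("chrom").size().sum() == 500


def test_annotation_rejects_single_gene():
    with pytest.raises(ValueError):
        make_annotation(1, 1, seed=0)


# ----------------------------------------------------------------- counts


def test_counts_null_model_means_match_baseline():
    truth = null_truth(n=1000, dispersion=1e-13, lib_size_range=(1.0, 1.0))
    design = [("L", "DMSO", r) for r in (1, 2, 3)] + [
        ("L", "TGFB1_MEKI", r) for r in (1, 2, 3)
    ]
    cm, gene_truth = simulate_counts(truth, design)
    ratio = cm.values.mean(axis=1) / gene_truth["baseline"]
    assert abs(ratio.mean() - 1.0) < 0.05


def test_counts_switch_block_fold_change():
    # Monte-Carlo over many replicate columns: double/DMSO mean ratio ~ 2**3
    genes = [f"G{i:05d}" for i in range(200)]
    truth = TruthSpec(
        gene_blocks={"switch_up": genes[:50], "null": genes[50:]},
        effect_sizes={"switch_up": {"TGFB1_MEKI": 3.0}},
        lib_size_range=(1.0, 1.0),
        seed=11,
    )
    design = [("L", t, r) for t in ("DMSO", "TGFB1_MEKI") for r in range(1, 61)]
    cm, _ = simulate_counts(truth, design)
    dmso = cm.samples.index[cm.samples["treatment"] == "DMSO"]
    dbl = cm.samples.index[cm.samples["treatment"] == "TGFB1_MEKI"]
    sw = truth.gene_blocks["switch_up"]
    ratio = cm.values.loc[sw, dbl].mean(axis=1) / cm.values.loc[sw, dmso].mean(axis=1)
    assert abs(ratio.mean() - 8.0) / 8.0 < 0.1


def test_counts_deterministic(small_truth, small_design):
    a, _ = simulate_counts(small_truth, small_design)
    b, _ = simulate_counts(small_truth, small_design)
    pd.testing.assert_frame_equal(a.values, b.values)


def test_counts_require_dmso_reference(small_truth):
    with pytest.raises(ValueError, match="invalid design"):
        simulate_counts(small_truth, [("L", "TGFB1", 1), ("L", "TGFB1", 2)])


# ------------------------------------------------------------------ peaks


def _consensus_counts(truth, annotation):
    sets, _ = simulate_peaks(truth, annotation, n_shared=200)
    cons = reproducible_peaks(sets["DMSO"]["ab1"], sets["DMSO"]["ab2"])
    return len(sets["DMSO"]["ab1"]), len(cons)


def test_peaks_full_reproducibility(small_annotation):
    truth = null_truth(n=400, reproducible_fraction=1.0)
    n_rep, n_cons = _consensus_counts(truth, small_annotation)
    assert n_cons == n_rep


def test_peaks_zero_reproducibility(small_annotation):
    truth = null_truth(n=400, reproducible_fraction=0.0)
    _, n_cons = _consensus_counts(truth, small_annotation)
    assert n_cons == 0


def test_peaks_half_reproducibility_binomial(small_annotation):
    from scipy import stats

    truth = null_truth(n=400, reproducible_fraction=0.5)
    sets, _ = simulate_peaks(truth, small_annotation, n_shared=200)
    # restrict to a condition with no unique loci beyond the shared 200+40
    cons = reproducible_peaks(sets["MEKI"]["ab1"], sets["MEKI"]["ab2"])
    n = len(sets["MEKI"]["ab1"].merged()) + len(sets["MEKI"]["ab2"].merged()) - len(cons)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
    assert lo <= len(cons) <= hi


def test_peaks_jittered_replicates_always_overlap(small_truth, small_annotation):
    sets, _ = simulate_peaks(small_truth, small_annotation)
    for cond, reps in sets.items():
        cons = reproducible_peaks(reps["ab1"], reps["ab2"])
        widths = cons.intervals["end"] - cons.intervals["start"]
        assert (widths >= 1).all()


# -------------------------------------------------------------- sequences


def test_sequences_full_implant_hits_at_max_score(small_truth, small_annotation):
    from apoptosig.motifs import PWM, scan_sequence

    truth = null_truth(n=400, motif_implant_rate=1.0)
    sets, _ = simulate_peaks(truth, small_annotation, n_shared=50)
    peaks = sets["DMSO"]["ab1"]
    fg, _ = simulate_peak_sequences(peaks, PWM_COUNTS, truth)
    pwm = PWM.from_counts("SBE_SMAD", PWM_COUNTS["SBE_SMAD"])
    for seq in fg.values():
        hits = scan_sequence(seq, pwm, score_fraction=1.0)
        assert any(s == pytest.approx(pwm.max_score()) for _, _, s in hits)


def test_sequences_no_implant_matches_background_rate(small_annotation):
    from apoptosig.motifs import PWM, scan_sequence

    truth = null_truth(n=400, motif_implant_rate=0.0)
    sets, _ = simulate_peaks(truth, small_annotation, n_shared=500)
    fg, bg = simulate_peak_sequences(sets["DMSO"]["ab1"], PWM_COUNTS, truth)
    pwm = PWM.from_counts("SBE_SMAD", PWM_COUNTS["SBE_SMAD"])
    fg_rate = np.mean([bool(scan_sequence(s, pwm)) for s in fg.values()])
    bg_rate = np.mean([bool(scan_sequence(s, pwm)) for s in bg.values()])
    assert abs(fg_rate - bg_rate) < 0.05


def test_sequences_deterministic(small_truth, small_annotation):
    sets, _ = simulate_peaks(small_truth, small_annotation, n_shared=30)
    fg1, bg1 = simulate_peak_sequences(sets["DMSO"]["ab1"], PWM_COUNTS, small_truth)
    fg2, bg2 = simulate_peak_sequences(sets["DMSO"]["ab1"], PWM_COUNTS, small_truth)
    assert fg1 == fg2 and bg1 == bg2


def test_dinucleotide_shuffle_preserves_dinucleotides(rng):
    from collections import Counter

    seq = "".join(rng.choice(list("ACGT"), size=300))
    shuf = synthetic._dinucleotide_shuffle(seq, rng)
    assert len(shuf) == len(seq)
    orig = Counter(zip(seq[:-1], seq[1:]))
    new = Counter(zip(shuf[:-1], shuf[1:]))
    assert orig == new


def test_sequences_reject_pwm_longer_than_peak(small_truth):
    from apoptosig.peaks import PeakSet
    import pandas as pd

    tiny = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5]}))
    with pytest.raises(ValueError, match="PWM"):
        simulate_peak_sequences(tiny, PWM_COUNTS, small_truth)


# ------------------------------------------------------------ single cell


def test_single_cell_null_shift_is_flat(small_truth):
    from apoptosig.signatures import module_score, score_by_state

    truth = TruthSpec(**{**small_truth.to_dict(), "sc_shift": 0.0})
    expr, labels = simulate_single_cell(truth, cells_per_state=80)
    scores = module_score(expr, set(truth.gene_blocks["switch_up"]), seed=0)
    per_state, _, _ = score_by_state(scores, labels)
    se = per_state["sd"] / np.sqrt(per_state["n"])
    spread = per_state["mean"].max() - per_state["mean"].min()
    assert spread < 2 * se.max() * 2  # |delta| < 2 SE on the difference


def test_single_cell_designated_state_scores_highest(small_truth):
    from apoptosig.signatures import module_score, score_by_state

    expr, labels = simulate_single_cell(small_truth, cells_per_state=80)
    scores = module_score(expr, set(small_truth.gene_blocks["switch_up"]), seed=0)
    _, argmax, tie = score_by_state(scores, labels)
    assert argmax == "NCSC" and not tie


def test_single_cell_requires_two_states(small_truth):
    with pytest.raises(ValueError):
        simulate_single_cell(small_truth, states=("NCSC",))


# ----------------------------------------------------------- dose response


def test_dose_response_noiseless_inversion():
    from apoptosig.doseresponse import fit_4pl

    truth = null_truth(
        dose_noise_sd=0.0,
        fourpl_params={"L": {"top": 1.0, "bottom": 0.2, "hill": 1.1, "ic50_molar": 2e-9}},
    )
    table = simulate_dose_response(truth, synthetic.DEFAULT_DOSES)
    pos = table[table["dose_molar"] > 0]
    fit = fit_4pl(pos["dose_molar"], pos["response"], cell_line="L")
    assert fit.ic50_molar == pytest.approx(2e-9, rel=1e-6)
    # with the vehicle rows anchored at log10 = -5 the fit is near-exact
    fit_v = fit_4pl(table["dose_molar"], table["response"], cell_line="L")
    assert np.log10(fit_v.ic50_molar) == pytest.approx(np.log10(2e-9), abs=0.01)


def test_dose_response_flat_line_has_undefined_ic50():
    from apoptosig.doseresponse import fit_4pl

    truth = null_truth(fourpl_params={"R": {"flat": True, "level": 1.0}})
    table = simulate_dose_response(truth, synthetic.DEFAULT_DOSES)
    fit = fit_4pl(table["dose_molar"], table["response"], cell_line="R")
    assert fit.flat_flag and not fit.ic50_defined


def test_dose_response_requires_four_doses(small_truth):
    with pytest.raises(ValueError, match="4"):
        simulate_dose_response(small_truth, [1e-9, 2e-9, 4e-9])


def test_dose_response_deterministic(small_truth):
    a = simulate_dose_response(small_truth, synthetic.DEFAULT_DOSES)
    b = simulate_dose_response(small_truth, synthetic.DEFAULT_DOSES)
    pd.testing.assert_frame_equal(a, b)


# --------------------------------------------------------- fixture bundle


def test_fixture_bundle_round_trips(tmp_path, small_truth):
    bundle = write_fixture_bundle(small_truth, tmp_path)
    counts = asio.read_counts_tsv(bundle.counts_tsv)
    cm, _ = simulate_counts(small_truth, synthetic.default_design())
    pd.testing.assert_frame_equal(counts, cm.values)

    sets, _ = simulate_peaks(small_truth, synthetic.make_annotation(400, 3, seed=7))
    bed = read_bed(bundle.peak_beds["DMSO/ab1"])
    pd.testing.assert_frame_equal(
        bed.intervals[["chrom", "start", "end"]],
        sets["DMSO"]["ab1"].intervals[["chrom", "start", "end"]],
    )

    assert synthetic.read_truth(bundle.truth_json) == small_truth
    gmt = asio.read_gmt(bundle.gmt_path)
    assert set(gmt["GO_NEG_REG_APOPTOSIS"]) <= set(gmt["GO_APOPTOTIC_PROCESS"])
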