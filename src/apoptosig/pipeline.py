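"""End-to-end orchestration of the apoptosis-signature pipeline.

Each stage reads its inputs from a working directory (fixture files or
user-supplied equivalents), writes its outputs to a stage subdirectory,
and contributes a summary block to the machine-readable run report.
Stage order: simulate -> de -> programs -> signatures -> peaks ->
integrate -> motifs -> doseresponse.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, integration, io as asio, motifs as motifmod
from . import peaks as peakmod, programs, signatures as sigmod, synthetic
from .doseresponse import classify_threshold, fit_dose_response_table

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_genes": 2000,
    "block_size": 60,
    "thresholds": {
        "padj": 0.05,
        "lfc": 1.0,
        "marker_lfc": 0.3,
        "marker_p": 0.05,
        "ic50_threshold_pm": 2000.0,
    },
    "cluster_k": {"M130830": 5, "M170117": 7},
    "great": {"basal_up": 5000, "basal_down": 1000, "max_extension": 1_000_000},
    "promoter_window": 1000,
    "gsea": {"n_perm": 999, "weight": 1.0},
    "module_score": {"n_bins": 24, "n_ctrl": 100},
    "single_cell": {"cells_per_state": 100},
    "doseresponse": {"flat_fraction": 0.2, "vehicle_log10_um": -5.0},
    "motifs": {"score_fraction": 0.8},
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict | None) -> dict:
    """Merge a user config over the defaults; unknown keys are rejected."""
    merged = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(dst: dict, src: dict, path: str = "") -> None:
        for key, val in src.items():
            if key not in dst:
                raise ConfigError(f"unknown config key {path + key!r}")
            if isinstance(dst[key], dict):
                if not isinstance(val, dict):
                    raise ConfigError(f"config key {path + key!r} must be a mapping")
                _merge(dst[key], val, path + key + ".")
            else:
                dst[key] = val

    if config:
        # cluster_k keys are user cell-line names, not fixed schema
        user = copy.deepcopy(config)
        ck = user.pop("cluster_k", None)
        _merge(merged, user)
        if ck is not None:
            merged["cluster_k"] = dict(ck)
    return merged


def _fixture_dir(workdir) -> Path:
    return Path(workdir) / "fixture"


# ---------------------------------------------------------------- stages


def stage_simulate(config: dict, workdir) -> dict:
    truth = synthetic.default_truth(
        n_genes=config["n_genes"], block_size=config["block_size"], seed=config["seed"]
    )
    synthetic.write_fixture_bundle(truth, _fixture_dir(workdir))
    # report file names only so the report stays byte-identical across workdirs
    return {"n_genes": config["n_genes"],
            "files": sorted(p.name for p in _fixture_dir(workdir).iterdir())}


def _load_counts(workdir) -> diffexpr.CountMatrix:
    fx = _fixture_dir(workdir)
    if not (fx / "counts.tsv").exists():
        raise FileNotFoundError(
            f"{fx / 'counts.tsv'} missing; run the 'simulate' stage first"
        )
    values = asio.read_counts_tsv(fx / "counts.tsv")
    sheet = asio.read_sample_sheet(fx / "samples.csv")
    return diffexpr.CountMatrix(values, sheet)


def stage_de(config: dict, workdir) -> dict:
    cm = _load_counts(workdir)
    outdir = Path(workdir) / "de"
    outdir.mkdir(parents=True, exist_ok=True)
    sf = diffexpr.estimate_size_factors(cm)
    disp = diffexpr.estimate_dispersions(cm, sf)
    summary = {}
    for line in sorted(cm.samples["cell_line"].unique()):
        for treatment in [t for t in diffexpr.TREATMENTS if t != "DMSO"]:
            table = diffexpr.de_test(
                cm, (line, treatment), size_factors=sf, dispersions=disp
            )
            diffexpr.write_de_table(table, outdir / f"{line}_{treatment}.tsv")
            n_sig = int((table["padj"] < config["thresholds"]["padj"]).sum())
            summary[f"{line}/{treatment}"] = {"n_tested": int(table["pvalue"].notna().sum()),
                                              "n_significant": n_sig}
    return summary


def _load_de_tables(workdir, line: str) -> dict[str, pd.DataFrame]:
    dedir = Path(workdir) / "de"
    tables = {}
    for treatment in [t for t in diffexpr.TREATMENTS if t != "DMSO"]:
        path = dedir / f"{line}_{treatment}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"{path} missing; run the 'de' stage first")
        tables[treatment] = diffexpr.read_de_table(path)
    return tables


def stage_programs(config: dict, workdir) -> dict:
    """Per-line clustering of significant genes and program GSEA."""
    cm = _load_counts(workdir)
    fx = _fixture_dir(workdir)
    gene_sets = {k: set(v) for k, v in asio.read_gmt(fx / "gene_sets.gmt").items()}
    sf = diffexpr.estimate_size_factors(cm)
    norm = cm.values / sf
    outdir = Path(workdir) / "programs"
    outdir.mkdir(parents=True, exist_ok=True)
    padj_t = config["thresholds"]["padj"]
    summary: dict = {}
    for line in sorted(cm.samples["cell_line"].unique()):
        tables = _load_de_tables(workdir, line)
        degs = sorted(
            set().union(*[set(t.index[t["padj"] < padj_t]) for t in tables.values()])
        )
        cols = {}
        for treatment in diffexpr.TREATMENTS:
            samp = cm.samples.index[
                (cm.samples["cell_line"] == line)
                & (cm.samples["treatment"] == treatment)
            ]
            cols[treatment] = norm.loc[degs, samp].mean(axis=1)
        cond_means = pd.DataFrame(cols)
        info: dict = {"n_degs": len(degs)}
        selected: set = set()
        if degs:
            z = programs.zscore_rows(np.log2(cond_means + 1.0))
            k = int(config["cluster_k"].get(line, 5))
            k = min(k, len(degs))
            groups = programs.cluster_and_cut(z, k)
            selected = programs.select_double_high_groups(groups)
            info["k"] = k
        (outdir / f"{line}_double_high_genes.txt").write_text(
            "\n".join(sorted(selected)) + "\n"
        )
        info["n_double_high"] = len(selected)
        # program enrichment on the TGFB1 and double-treatment rankings
        es_block = {}
        for treatment in ("TGFB1", "TGFB1_MEKI"):
            ranked, metric = programs.rank_by_lfc(tables[treatment], padj_t)
            if ranked and gene_sets["AXL_PROGRAM"] & set(ranked):
                res = programs.gsea_permutation(
                    ranked,
                    metric,
                    gene_sets["AXL_PROGRAM"],
                    n_perm=int(config["gsea"]["n_perm"]),
                    seed=config["seed"],
                    weight=float(config["gsea"]["weight"]),
                )
                es_block[treatment] = {
                    "es": res.es,
                    "nes": res.nes,
                    "pvalue": res.pvalue,
                    "n_ranked": len(ranked),
                }
        info["axl_program_enrichment"] = es_block
        summary[line] = info
    return summary


def stage_signatures(config: dict, workdir) -> dict:
    cm = _load_counts(workdir)
    fx = _fixture_dir(workdir)
    truth = synthetic.read_truth(fx / "truth.json")
    outdir = Path(workdir) / "signatures"
    outdir.mkdir(parents=True, exist_ok=True)
    expr, labels = synthetic.simulate_single_cell(
        truth, cells_per_state=int(config["single_cell"]["cells_per_state"])
    )
    summary: dict = {}
    for line in sorted(cm.samples["cell_line"].unique()):
        tables = _load_de_tables(workdir, line)
        sigs = sigmod.derive_treatment_signatures(
            tables,
            padj_threshold=config["thresholds"]["padj"],
            lfc_threshold=config["thresholds"]["lfc"],
        )
        asio.write_gmt(sigmod.signatures_to_gmt(sigs), outdir / f"{line}_signatures.gmt")
        line_info: dict = {}
        for treatment, sig in sigs.items():
            scores = sigmod.module_score(
                expr,
                sig,
                n_bins=int(config["module_score"]["n_bins"]),
                n_ctrl=int(config["module_score"]["n_ctrl"]),
                seed=config["seed"],
            )
            per_state, argmax, tie = sigmod.score_by_state(scores, labels)
            out = pd.DataFrame({"cell": scores.index, "score": scores.to_numpy(),
                                "state": labels.to_numpy()})
            out.to_csv(outdir / f"{line}_{treatment}_module_scores.tsv", sep="\t", index=False)
            line_info[treatment] = {
                "size": len(sig.members),
                "argmax_state": argmax,
                "tie": tie,
                "state_means": per_state["mean"].round(4).to_dict(),
            }
        summary[line] = line_info
    return summary


def stage_peaks(config: dict, workdir) -> dict:
    fx = _fixture_dir(workdir)
    annotation = asio.read_annotation(fx / "annotation.tsv")
    outdir = Path(workdir) / "peaks"
    outdir.mkdir(parents=True, exist_ok=True)
    consensus = {}
    for cond in diffexpr.TREATMENTS:
        rep_a = peakmod.read_bed(fx / f"peaks_{cond}_ab1.bed")
        rep_b = peakmod.read_bed(fx / f"peaks_{cond}_ab2.bed")
        cons = peakmod.reproducible_peaks(rep_a, rep_b)
        peakmod.write_bed(cons, outdir / f"consensus_{cond}.bed")
        consensus[cond] = cons
    partition = peakmod.multiway_membership(consensus)
    # drop few-bp slivers at jittered boundaries: unique regions keep
    # whole-peak semantics for gene association
    unique = {
        cond: ps.filter_min_width(50)
        for cond, ps in partition.unique_sets().items()
    }
    for cond, ps in unique.items():
        peakmod.write_bed(ps, outdir / f"unique_{cond}.bed")
    domains = peakmod.regulatory_domains(
        annotation,
        basal_up=int(config["great"]["basal_up"]),
        basal_down=int(config["great"]["basal_down"]),
        max_extension=int(config["great"]["max_extension"]),
        chrom_sizes=synthetic.infer_chrom_sizes(annotation),
    )
    summary: dict = {"consensus_counts": {c: len(p) for c, p in consensus.items()},
                     "unique_counts": {c: len(p) for c, p in unique.items()}}
    gene_sets = {}
    for cond in diffexpr.TREATMENTS:
        genes_all, _, _ = peakmod.peaks_to_genes(consensus[cond], domains)
        genes_unique, _, _ = peakmod.peaks_to_genes(unique[cond], domains)
        gene_sets[cond] = genes_all
        (outdir / f"peak_genes_unique_{cond}.txt").write_text(
            "\n".join(sorted(genes_unique)) + "\n"
        )
        summary.setdefault("peak_gene_counts", {})[cond] = {
            "associated": len(genes_all),
            "unique_region_genes": len(genes_unique),
        }
    cats = peakmod.annotate_peaks(
        consensus["TGFB1_MEKI"], annotation, promoter_window=int(config["promoter_window"])
    )
    summary["double_peak_categories"] = cats.value_counts().to_dict()
    return summary


def stage_integrate(config: dict, workdir) -> dict:
    fx = _fixture_dir(workdir)
    gene_sets = asio.read_gmt(fx / "gene_sets.gmt")
    universe = integration.build_apoptosis_universe(
        gene_sets["GO_APOPTOTIC_PROCESS"], gene_sets["GO_NEG_REG_APOPTOSIS"]
    )
    progdir = Path(workdir) / "programs"
    peakdir = Path(workdir) / "peaks"
    lines = sorted(
        p.name.split("_double_high_genes")[0]
        for p in progdir.glob("*_double_high_genes.txt")
    )
    if len(lines) < 2:
        raise FileNotFoundError("need the 'programs' stage outputs for two cell lines")
    line_a, line_b = lines[0], lines[1]
    deg_a = set((progdir / f"{line_a}_double_high_genes.txt").read_text().split())
    deg_b = set((progdir / f"{line_b}_double_high_genes.txt").read_text().split())
    peak_path = peakdir / "peak_genes_unique_TGFB1_MEKI.txt"
    if not peak_path.exists():
        raise FileNotFoundError(f"{peak_path} missing; run the 'peaks' stage first")
    peak_genes = set(peak_path.read_text().split())
    partition = integration.venn_partition(
        {
            "deg_line_a": deg_a,
            "deg_line_b": deg_b,
            "peak_genes": peak_genes,
            "apoptosis_universe": universe.members,
        }
    )
    signature = integration.assemble_apoptosis_signature(partition)
    outdir = Path(workdir) / "integrate"
    outdir.mkdir(parents=True, exist_ok=True)
    members = sorted(signature.members) if signature else []
    prov = signature.provenance if signature else {}
    asio.write_json(
        {"members": members, "provenance": prov},
        outdir / "apoptosis_signature.json",
    )
    summary = {
        "lines": [line_a, line_b],
        "venn_counts": partition.counts(),
        "signature_size": len(members),
    }
    truth_path = fx / "truth.json"
    if truth_path.exists():
        payload = asio.read_json(truth_path)
        truth = synthetic.TruthSpec.from_dict(payload["truth_spec"])
        switch = set(truth.gene_blocks["switch_up"])
        expected = (
            set(payload["peaks"]["double_unique_target_genes"])
            & integration.normalize_symbols(universe.members)
        )
        got = set(members)
        sens = len(got & expected) / len(expected) if expected else float("nan")
        contamination = len(got - switch) / len(got) if got else 0.0
        summary["truth_recovery"] = {
            "n_expected": len(expected),
            "sensitivity": sens,
            "contamination": contamination,
        }
    return summary


def stage_motifs(config: dict, workdir) -> dict:
    fx = _fixture_dir(workdir)
    fg = asio.read_fasta(fx / "peaks_double_unique.fa")
    bg = asio.read_fasta(fx / "background.fa")
    pwms = motifmod.pwms_from_jaspar(asio.read_jaspar(fx / "motifs.jaspar"))
    table = motifmod.motif_enrichment(
        fg, bg, pwms, score_fraction=float(config["motifs"]["score_fraction"])
    )
    outdir = Path(workdir) / "motifs"
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "enrichment.tsv", sep="\t")
    return {
        "n_foreground": len(fg),
        "n_background": len(bg),
        "top_motif": table.index[0],
        "table": table.round(6).reset_index().to_dict(orient="records"),
    }


def stage_doseresponse(config: dict, workdir) -> dict:
    fx = _fixture_dir(workdir)
    table = asio.read_dose_response(fx / "dose_response.csv")
    fits = fit_dose_response_table(
        table,
        seed=config["seed"],
        vehicle_log10_um=float(config["doseresponse"]["vehicle_log10_um"]),
        flat_fraction=float(config["doseresponse"]["flat_fraction"]),
    )
    threshold = float(config["thresholds"]["ic50_threshold_pm"]) * 1e-12
    rows = []
    for line in sorted(fits):
        f = fits[line]
        label = classify_threshold(f, threshold)
        rows.append(
            {
                "cell_line": line,
                "ic50_molar": f.ic50_molar,
                "flat": f.flat_flag,
                "label": label,
            }
        )
    outdir = Path(workdir) / "doseresponse"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(outdir / "fits.tsv", sep="\t", index=False)
    return {"classification": rows}


STAGES = {
    "simulate": stage_simulate,
    "de": stage_de,
    "programs": stage_programs,
    "signatures": stage_signatures,
    "peaks": stage_peaks,
    "integrate": stage_integrate,
    "motifs": stage_motifs,
    "doseresponse": stage_doseresponse,
}

STAGE_ORDER = list(STAGES)


def run_stage(name: str, config: dict, workdir) -> dict:
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}")
    t0 = time.time()
    logger.info("stage %s: start", name)
    summary = STAGES[name](config, workdir)
    logger.info("stage %s: done in %.1fs", name, time.time() - t0)
    return summary


def run_all(config: dict | None, workdir) -> dict:
    """Run every stage in order and write the JSON run report.

    A stage failure is recorded in the (partial) report and re-raised
    after the report is written.
    """
    config = validate_config(config)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config,
        "stages": {},
        "failure": None,
    }
    failure: Exception | None = None
    for name in STAGE_ORDER:
        try:
            report["stages"][name] = run_stage(name, config, workdir)
        except Exception as exc:  # record, stop, report
            logger.error("stage %s failed: %s", name, exc)
            report["failure"] = {"stage": name, "error": str(exc)}
            failure = exc
            break
    asio.write_json(report, workdir / "report.json")
    if failure is not None:
        raise failure
    return report
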