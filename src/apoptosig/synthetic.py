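"""Synthetic pipeline inputs with known ground truth.

Every generator is a pure function of a :class:`TruthSpec` (plus explicit
arguments); randomness flows from the spec's root seed through fixed
``SeedSequence`` spawn keys, one per sub-generator:

====  =========================
key   sub-generator
====  =========================
0     make_annotation
1     simulate_counts
2     simulate_peaks
3     simulate_peak_sequences
4     simulate_single_cell
5     simulate_dose_response
====  =========================

The default spec emulates the study conditions: four treatments
(DMSO, TGFB1, MEKI, TGFB1_MEKI) x two cell lines x three replicates of
NB-distributed bulk counts with three implanted gene blocks — a
pro-invasive block up under TGFB1 only (and repressed in the double
treatment), a pro-apoptotic "switch" block up in the double treatment
only, and a MEKi-responsive MITF-like block — plus two-antibody SMAD4
peak replicates with a controlled reproducible fraction, condition-unique
peaks placed in regulatory range of the designated target genes, PWM
instances implanted in foreground peak sequences, four cell states of
log-normal single-cell expression, and 4PL viability curves including
flat (unfittable) resistant lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as asio
from .diffexpr import CountMatrix, TREATMENTS
from .peaks import PeakSet, write_bed

CELL_LINES = ("M130830", "M170117")
SC_STATES = ("pigmented", "SMC", "NCSC", "invasive")
ANTIBODIES = ("ab1", "ab2")

#: motif count matrices (rows A/C/G/T).  The target motif is a SMAD
#: binding element (palindromic GTCTAGAC core); the others are an AP-1
#: like TRE site and a uniform decoy.
PWM_COUNTS = {
    "SBE_SMAD": np.array(
        [
            [1, 1, 1, 18, 1, 17, 1, 2],
            [1, 1, 16, 1, 1, 1, 17, 1],
            [16, 1, 1, 1, 1, 1, 1, 16],
            [2, 17, 2, 0, 17, 1, 1, 1],
        ]
    ),
    "AP1_TRE": np.array(
        [
            [1, 1, 17, 1, 1, 1, 16],
            [1, 1, 1, 16, 1, 17, 1],
            [1, 16, 1, 1, 1, 1, 2],
            [17, 2, 1, 2, 17, 1, 1],
        ]
    ),
    "DECOY_UNIF": np.full((4, 8), 5),
}


@dataclass
class TruthSpec:
    """Ground-truth parameterisation of the synthetic study."""

    gene_blocks: dict[str, list[str]]
    effect_sizes: dict[str, dict[str, float]]
    dispersion: float | dict[str, float] = 0.05
    lib_size_range: tuple[float, float] = (0.7, 1.4)
    reproducible_fraction: float = 0.85
    unique_target_fraction: float = 1.0
    motif_implant_rate: float = 0.8
    fourpl_params: dict[str, dict] = field(default_factory=dict)
    dose_noise_sd: float = 0.02
    sc_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.gene_blocks.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"gene blocks overlap at {sorted(overlap)[:3]}")
            seen |= set(genes)
        for frac in (
            self.reproducible_fraction,
            self.unique_target_fraction,
            self.motif_implant_rate,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        disp = (
            self.dispersion.values()
            if isinstance(self.dispersion, dict)
            else [self.dispersion]
        )
        if any(a <= 0 for a in disp):
            raise ValueError("dispersion must be > 0")
        for block in self.effect_sizes.values():
            if any(not np.isfinite(v) for v in block.values()):
                raise ValueError("effect sizes must be finite")

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for block in self.gene_blocks.values():
            out.extend(block)
        return sorted(out)

    def block_of(self) -> dict[str, str]:
        return {g: b for b, genes in self.gene_blocks.items() for g in genes}

    def lfc(self, gene_block: str, treatment: str) -> float:
        return float(self.effect_sizes.get(gene_block, {}).get(treatment, 0.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lib_size_range"] = list(self.lib_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSpec":
        d = dict(d)
        d["lib_size_range"] = tuple(d["lib_size_range"])
        return cls(**d)


def _rng(truth: TruthSpec, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(truth.seed, spawn_key=(key,)))


def default_truth(n_genes: int = 2000, block_size: int = 60, seed: int = 0) -> TruthSpec:
    """The default study conditions (see module docstring)."""
    if n_genes < 4 * block_size:
        raise ValueError("n_genes too small for the default blocks")
    symbols = [f"G{i:05d}" for i in range(n_genes)]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    picked = rng.choice(n_genes, size=3 * block_size, replace=False)
    inv = [symbols[i] for i in picked[:block_size]]
    switch = [symbols[i] for i in picked[block_size : 2 * block_size]]
    mitf = [symbols[i] for i in picked[2 * block_size :]]
    null = [s for s in symbols if s not in set(inv) | set(switch) | set(mitf)]
    return TruthSpec(
        gene_blocks={
            "invasive_up": inv,
            "switch_up": switch,
            "mitf": mitf,
            "null": null,
        },
        effect_sizes={
            "invasive_up": {"TGFB1": 2.0, "TGFB1_MEKI": -1.0},
            "switch_up": {"TGFB1_MEKI": 3.0},
            "mitf": {"MEKI": 1.5},
        },
        fourpl_params={
            "M130830": {"top": 1.0, "bottom": 0.15, "hill": 1.2, "ic50_molar": 5e-10},
            "M161201": {"top": 1.0, "bottom": 0.2, "hill": 1.0, "ic50_molar": 1.5e-9},
            "M010817": {"top": 1.0, "bottom": 0.3, "hill": 1.0, "ic50_molar": 5e-8},
            "MM150543": {"top": 1.0, "bottom": 0.35, "hill": 0.9, "ic50_molar": 1e-7},
            "M170117": {"flat": True, "level": 0.97},
            "MM140325": {"flat": True, "level": 1.02},
        },
        seed=seed,
    )


def default_design(
    cell_lines=CELL_LINES, treatments=TREATMENTS, n_replicates: int = 3
) -> list[tuple[str, str, int]]:
    return [
        (cl, tr, r)
        for cl in cell_lines
        for tr in treatments
        for r in range(1, n_replicates + 1)
    ]


# ------------------------------------------------------------ annotation


def make_annotation(n_genes: int, n_chroms: int, seed: int) -> pd.DataFrame:
    """Random gene annotation: symbol, chrom, TSS, strand, gene interval,
    plus a simple two-exon structure (exon_starts / exon_ends columns).

    TSSs are spaced >= 45 kb apart so no two genes share a TSS and
    neighbouring regulatory domains are unambiguous.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes (neighbour-dependent rules)")
    if n_chroms < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    base = n_genes // n_chroms
    counts = [base] * n_chroms
    for i in range(n_genes - base * n_chroms):
        counts[i] += 1
    rows = []
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 60_000
        for _ in range(counts[ci]):
            tss = pos + int(rng.integers(0, 10_000))
            strand = "+" if rng.random() < 0.5 else "-"
            glen = int(rng.integers(2_000, 20_000))
            if strand == "+":
                start, end = tss, tss + glen
            else:
                start, end = tss - glen, tss
            e1 = int(rng.integers(200, 800))
            e2 = int(rng.integers(200, 800))
            rows.append(
                (
                    f"G{gi:05d}",
                    chrom,
                    tss,
                    strand,
                    start,
                    end,
                    f"{start},{end - e2}",
                    f"{start + e1},{end}",
                )
            )
            gi += 1
            pos = tss + 45_000
    return pd.DataFrame(
        rows,
        columns=[
            "symbol",
            "chrom",
            "tss",
            "strand",
            "start",
            "end",
            "exon_starts",
            "exon_ends",
        ],
    )


def infer_chrom_sizes(annotation: pd.DataFrame, pad: int = 100_000) -> dict[str, int]:
    return {
        chrom: int(sub["end"].max()) + pad
        for chrom, sub in annotation.groupby("chrom")
    }


# ---------------------------------------------------------------- counts


def simulate_counts(
    truth: TruthSpec, design: list[tuple[str, str, int]]
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts: mean = s_j * q_g * 2**LFC(block(g), treatment_j),
    variance = mu + alpha * mu**2.

    Returns the count matrix and a per-gene truth table (block, baseline).
    """
    lines = {cl for cl, _, _ in design}
    for cl in lines:
        if not any(c == cl and t == "DMSO" for c, t, _ in design):
            raise ValueError(f"invalid design: cell line {cl} has no DMSO sample")
    rng = _rng(truth, 1)
    genes = truth.genes
    block_of = truth.block_of()
    n_genes = len(genes)
    q = np.exp(rng.uniform(np.log(20.0), np.log(2000.0), size=n_genes))
    if isinstance(truth.dispersion, dict):
        alpha = np.array([truth.dispersion[g] for g in genes])
    else:
        alpha = np.full(n_genes, float(truth.dispersion))
    lo, hi = truth.lib_size_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(design)))

    cols = {}
    sheet_rows = []
    for j, (cl, tr, rep) in enumerate(design):
        lfc = np.array([truth.lfc(block_of[g], tr) for g in genes])
        mu = s[j] * q * 2.0**lfc
        tiny = alpha < 1e-12
        counts = np.empty(n_genes, dtype=np.int64)
        if tiny.any():
            counts[tiny] = rng.poisson(mu[tiny])
        if (~tiny).any():
            r = 1.0 / alpha[~tiny]
            p = r / (r + mu[~tiny])
            counts[~tiny] = rng.negative_binomial(r, p)
        name = f"{cl}_{tr}_r{rep}"
        cols[name] = counts
        sheet_rows.append((name, cl, tr, rep))
    values = pd.DataFrame(cols, index=genes)
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample", "cell_line", "treatment", "replicate"]
    ).set_index("sample")
    gene_truth = pd.DataFrame(
        {"block": [block_of[g] for g in genes], "baseline": q}, index=genes
    )
    cm = CountMatrix(values, sheet, gene_blocks=dict(zip(genes, gene_truth["block"])))
    return cm, gene_truth


# ----------------------------------------------------------------- peaks

#: which gene block each condition's unique peaks target
CONDITION_TARGETS = {
    "DMSO": "null",
    "TGFB1": "invasive_up",
    "MEKI": "mitf",
    "TGFB1_MEKI": "switch_up",
}


def simulate_peaks(
    truth: TruthSpec,
    annotation: pd.DataFrame,
    n_shared: int = 100,
    peak_width: int = 400,
    tss_offset: int = 15_000,
) -> tuple[dict[str, dict[str, PeakSet]], dict]:
    """Per condition x antibody replicate peak sets.

    Shared peaks occur in every condition; condition-unique peaks are
    placed within ``tss_offset`` of the TSS of that condition's target
    block genes.  A ``reproducible_fraction`` of each condition's peaks
    appears (jittered, always overlapping) in both antibody replicates;
    the rest land in one replicate only.  Returns the peak sets plus a
    truth record of the double-treatment unique target genes.
    """
    if annotation.empty:
        raise ValueError("annotation must be nonempty")
    rng = _rng(truth, 2)
    sizes = infer_chrom_sizes(annotation)
    ann = annotation.set_index("symbol")

    # shared loci: random positions away from any TSS +- 25 kb
    tss_by_chrom = {
        c: sub["tss"].to_numpy() for c, sub in annotation.groupby("chrom")
    }
    chroms = sorted(sizes)
    shared = []
    centers: dict[str, list[int]] = {c: [] for c in chroms}
    while len(shared) < n_shared:
        chrom = chroms[int(rng.integers(len(chroms)))]
        center = int(rng.integers(peak_width, sizes[chrom] - peak_width))
        if np.min(np.abs(tss_by_chrom[chrom] - center)) < 25_000:
            continue
        # keep shared loci mutually disjoint (simplifies count accounting)
        if centers[chrom] and np.min(np.abs(np.array(centers[chrom]) - center)) < 3 * peak_width:
            continue
        centers[chrom].append(center)
        shared.append((chrom, center - peak_width // 2, center + peak_width // 2))

    block_genes = {b: list(g) for b, g in truth.gene_blocks.items()}
    unique_loci: dict[str, list[tuple[str, int, int]]] = {}
    double_targets: list[str] = []
    nonunique_loci: list[tuple[str, int, int]] = []  # double peaks also in DMSO
    for cond, block in CONDITION_TARGETS.items():
        genes = block_genes.get(block, [])
        if cond == "DMSO":
            genes = genes[:40]  # a modest set of null-gene targets
        loci = []
        for g in genes:
            row = ann.loc[g]
            off = int(rng.integers(-tss_offset, tss_offset + 1))
            center = max(peak_width, int(row["tss"]) + off)
            locus = (row["chrom"], center - peak_width // 2, center + peak_width // 2)
            if cond == "TGFB1_MEKI" and rng.random() >= truth.unique_target_fraction:
                nonunique_loci.append(locus)
            else:
                loci.append(locus)
                if cond == "TGFB1_MEKI":
                    double_targets.append(g)
        unique_loci[cond] = loci

    jitter_max = peak_width // 4
    out: dict[str, dict[str, PeakSet]] = {}
    for cond in CONDITION_TARGETS:
        loci = shared + unique_loci[cond]
        if cond in ("TGFB1_MEKI", "DMSO"):
            loci = loci + nonunique_loci
        reps: dict[str, list] = {ab: [] for ab in ANTIBODIES}
        for chrom, s0, e0 in loci:
            if rng.random() < truth.reproducible_fraction:
                for ab in ANTIBODIES:
                    js = int(rng.integers(-jitter_max, jitter_max + 1))
                    je = int(rng.integers(-jitter_max, jitter_max + 1))
                    reps[ab].append((chrom, max(0, s0 + js), e0 + je))
            else:
                ab = ANTIBODIES[int(rng.integers(2))]
                reps[ab].append((chrom, s0, e0))
        out[cond] = {
            ab: PeakSet(
                pd.DataFrame(reps[ab], columns=["chrom", "start", "end"])
                .sort_values(["chrom", "start"])
                .reset_index(drop=True)
            )
            for ab in ANTIBODIES
        }
    truth_record = {
        "double_unique_target_genes": sorted(double_targets),
        "n_shared": n_shared,
        "peak_width": peak_width,
    }
    return out, truth_record


# ------------------------------------------------------------- sequences

_BASES = np.array(list("ACGT"))


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 100) -> str:
    """Eulerian-walk shuffle preserving the dinucleotide multiset."""
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq[:-1], seq[1:]):
            edges.setdefault(a, []).append(b)
        for lst in edges.values():
            rng.shuffle(lst)
        walk = [seq[0]]
        cur = seq[0]
        n_edges = len(seq) - 1
        stacks = {k: list(v) for k, v in edges.items()}
        for _ in range(n_edges):
            nxt_list = stacks.get(cur)
            if not nxt_list:
                break
            cur = nxt_list.pop()
            walk.append(cur)
        if len(walk) == len(seq):
            return "".join(walk)
    # degenerate composition: fall back to a plain shuffle
    arr = np.array(list(seq))
    rng.shuffle(arr)
    return "".join(arr)


def pwm_consensus(counts: np.ndarray) -> str:
    return "".join(_BASES[np.argmax(np.asarray(counts, dtype=float), axis=0)])


def simulate_peak_sequences(
    peaks: PeakSet,
    pwm_counts: dict[str, np.ndarray],
    truth: TruthSpec,
    target_pwm: str = "SBE_SMAD",
) -> tuple[dict[str, str], dict[str, str]]:
    """Foreground sequences (one per peak, PWM consensus implanted at
    ``motif_implant_rate``) and dinucleotide-shuffled backgrounds."""
    widths = (peaks.intervals["end"] - peaks.intervals["start"]).to_numpy()
    max_len = max(m.shape[1] for m in pwm_counts.values())
    if len(widths) and widths.min() < max_len:
        raise ValueError("a PWM is longer than the shortest peak")
    rng = _rng(truth, 3)
    motif = pwm_consensus(pwm_counts[target_pwm])
    fg: dict[str, str] = {}
    bg: dict[str, str] = {}
    for i, w in enumerate(widths):
        seq = "".join(rng.choice(_BASES, size=int(w)))
        if rng.random() < truth.motif_implant_rate:
            pos = int(rng.integers(0, int(w) - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif) :]
        name = f"peak_{i + 1}"
        fg[name] = seq
        bg[f"{name}_shuf"] = _dinucleotide_shuffle(seq, rng)
    return fg, bg


# ------------------------------------------------------------ single cell


def simulate_single_cell(
    truth: TruthSpec,
    states: tuple[str, ...] = SC_STATES,
    cells_per_state: int = 100,
    state_programs: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal cells x genes expression with state-specific block shifts.

    By default the NCSC state over-expresses the switch_up block by
    ``truth.sc_shift`` (the invasive state the invasive block, pigmented
    the MITF block).  Returns (expression, state labels).
    """
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    if state_programs is None:
        state_programs = {
            "NCSC": "switch_up",
            "invasive": "invasive_up",
            "pigmented": "mitf",
        }
    rng = _rng(truth, 4)
    genes = truth.genes
    block_of = truth.block_of()
    base = rng.normal(1.0, 0.5, size=len(genes))
    rows = []
    labels = []
    cell_names = []
    for state in states:
        shift_blocks = {state_programs.get(state)}
        shift = np.array(
            [truth.sc_shift if block_of[g] in shift_blocks else 0.0 for g in genes]
        )
        for c in range(cells_per_state):
            rows.append(base + shift + rng.normal(0.0, 0.4, size=len(genes)))
            labels.append(state)
            cell_names.append(f"{state}_{c + 1}")
    expr = pd.DataFrame(np.array(rows), index=cell_names, columns=genes)
    return expr, pd.Series(labels, index=cell_names, name="state")


# ---------------------------------------------------------- dose response


def fourpl_curve(dose_molar, top, bottom, hill, ic50_molar):
    d = np.asarray(dose_molar, dtype=float)
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log10(d), -np.inf)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - np.log10(ic50_molar))))


def simulate_dose_response(
    truth: TruthSpec, doses: list[float], n_replicates: int = 3
) -> pd.DataFrame:
    """Viability table cell_line,dose_molar,replicate,response.

    ``doses`` must contain >=4 distinct positive concentrations; a vehicle
    (dose 0) row is required and added if absent.  Flat-flagged lines give
    dose-independent responses.
    """
    positive = sorted({d for d in doses if d > 0})
    if len(positive) < 4:
        raise ValueError("need >=4 distinct positive doses (4 free parameters)")
    all_doses = [0.0] + positive if 0.0 not in doses else sorted(set(doses))
    rng = _rng(truth, 5)
    rows = []
    for line, params in truth.fourpl_params.items():
        for d in all_doses:
            if params.get("flat"):
                mean = params.get("level", 1.0)
            else:
                mean = float(
                    fourpl_curve(
                        d, params["top"], params["bottom"], params["hill"], params["ic50_molar"]
                    )
                )
            for rep in range(1, n_replicates + 1):
                resp = mean + rng.normal(0.0, truth.dose_noise_sd)
                rows.append((line, d, rep, resp))
    return pd.DataFrame(rows, columns=["cell_line", "dose_molar", "replicate", "response"])


DEFAULT_DOSES = [16e-12 * 4.0**k for k in range(8)]  # 16 pM .. ~262 nM


# --------------------------------------------------------- fixture bundle


@dataclass
class FixtureBundle:
    counts_tsv: str
    sample_sheet: str
    annotation: str
    peak_beds: dict[str, str]  # "{condition}/{antibody}" -> path
    gmt_path: str
    pwm_path: str
    fasta_fg: str
    fasta_bg: str
    dose_csv: str
    truth_json: str


def default_gene_sets(truth: TruthSpec, rng: np.random.Generator) -> dict[str, list[str]]:
    """Curated gene-set universes mirroring the study's inputs: melanoma
    programs, a GO-style apoptosis set and its negative-regulation subset."""
    blocks = truth.gene_blocks
    null = list(blocks["null"])
    pick = lambda n, pool: [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
    neg_reg = pick(30, null)
    apoptosis = sorted(set(blocks["switch_up"]) | set(pick(100, null)) | set(neg_reg))
    return {
        "AXL_PROGRAM": sorted(set(blocks["invasive_up"]) | set(pick(20, null))),
        "MITF_PROGRAM": sorted(blocks["mitf"]),
        "HOEK_INVASIVE": sorted(set(blocks["invasive_up"][:40]) | set(pick(15, null))),
        "VERFAILLIE_INVASIVE": sorted(set(blocks["invasive_up"][20:]) | set(pick(15, null))),
        "GO_APOPTOTIC_PROCESS": apoptosis,
        "GO_NEG_REG_APOPTOSIS": sorted(neg_reg),
    }


def write_fixture_bundle(truth: TruthSpec, outdir) -> FixtureBundle:
    """Generate and write every pipeline input plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_genes = len(truth.genes)
    annotation = make_annotation(n_genes, n_chroms=3, seed=truth.seed)
    # annotation symbols are G00000.. by construction, matching default_truth
    cm, gene_truth = simulate_counts(truth, default_design())
    peak_sets, peak_truth = simulate_peaks(truth, annotation)
    gene_sets = default_gene_sets(truth, _rng(truth, 6))

    asio.write_counts_tsv(cm.values, outdir / "counts.tsv")
    asio.write_sample_sheet(cm.samples, outdir / "samples.csv")
    asio.write_annotation(annotation, outdir / "annotation.tsv")
    bed_paths = {}
    for cond, reps in peak_sets.items():
        for ab, ps in reps.items():
            path = outdir / f"peaks_{cond}_{ab}.bed"
            write_bed(ps, path)
            bed_paths[f"{cond}/{ab}"] = str(path)
    asio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    asio.write_jaspar(PWM_COUNTS, outdir / "motifs.jaspar")

    from .peaks import reproducible_peaks, multiway_membership

    consensus = {
        cond: reproducible_peaks(reps["ab1"], reps["ab2"])
        for cond, reps in peak_sets.items()
    }
    unique_double = (
        multiway_membership(consensus)
        .unique_sets()["TGFB1_MEKI"]
        .filter_min_width(50)
    )
    fg, bg = simulate_peak_sequences(unique_double, PWM_COUNTS, truth)
    asio.write_fasta(fg, outdir / "peaks_double_unique.fa")
    asio.write_fasta(bg, outdir / "background.fa")

    dose = simulate_dose_response(truth, DEFAULT_DOSES)
    asio.write_dose_response(dose, outdir / "dose_response.csv")

    truth_payload = {
        "truth_spec": truth.to_dict(),
        "peaks": peak_truth,
        "gene_baseline": gene_truth["baseline"].round(4).to_dict(),
    }
    asio.write_json(truth_payload, outdir / "truth.json")
    return FixtureBundle(
        counts_tsv=str(outdir / "counts.tsv"),
        sample_sheet=str(outdir / "samples.csv"),
        annotation=str(outdir / "annotation.tsv"),
        peak_beds=bed_paths,
        gmt_path=str(outdir / "gene_sets.gmt"),
        pwm_path=str(outdir / "motifs.jaspar"),
        fasta_fg=str(outdir / "peaks_double_unique.fa"),
        fasta_bg=str(outdir / "background.fa"),
        dose_csv=str(outdir / "dose_response.csv"),
        truth_json=str(outdir / "truth.json"),
    )


def read_truth(path) -> TruthSpec:
    payload = asio.read_json(path)
    return TruthSpec.from_dict(payload["truth_spec"])
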