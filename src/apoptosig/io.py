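"""File formats used across the pipeline.

Counts travel as TSV (gene symbol index) or MatrixMarket with row/column
sidecars; peaks as 6-column BED (0-based half-open); gene sets as GMT;
position weight matrices as JASPAR text (parsed with Biopython); sequences
as FASTA; dose-response tables and sample sheets as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

# ---------------------------------------------------------------- counts


def write_counts_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    df.index.name = None
    return df


def write_counts_mtx(values: pd.DataFrame, prefix) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.txt`` / ``.samples.txt``."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(values.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(values.index) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(values.columns) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=genes, columns=samples).astype(int)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample")


# ------------------------------------------------------------ annotation

ANNOTATION_COLUMNS = ["symbol", "chrom", "tss", "strand", "start", "end"]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation lacks columns {sorted(missing)}")
    return ann


# ------------------------------------------------------------------ GMT


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "apoptosig"] + list(members)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# ----------------------------------------------------------------- PWMs


def write_jaspar(pwm_counts: dict[str, np.ndarray], path) -> None:
    """Write count matrices (4 x L, rows A/C/G/T) in JASPAR text format."""
    with open(path, "w") as fh:
        for name, mat in pwm_counts.items():
            fh.write(f">{name}\n")
            for base, row in zip("ACGT", np.asarray(mat)):
                cells = " ".join(f"{v:6.0f}" for v in row)
                fh.write(f"{base} [ {cells} ]\n")


def read_jaspar(path) -> list:
    """Parse JASPAR-format motifs (Biopython motif objects)."""
    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))


# ---------------------------------------------------------------- FASTA


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -------------------------------------------------------- dose-response

DOSE_COLUMNS = ["cell_line", "dose_molar", "replicate", "response"]


def write_dose_response(table: pd.DataFrame, path) -> None:
    table[DOSE_COLUMNS].to_csv(path, index=False)


def read_dose_response(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(DOSE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"dose-response table lacks columns {sorted(missing)}")
    return table


# ----------------------------------------------------------------- JSON


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
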