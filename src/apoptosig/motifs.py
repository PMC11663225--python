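"""Known-motif enrichment in peak sequences.

PWM log-odds scanning of both strands with a score threshold at a
fraction of the maximum attainable log-odds, then a one-sided
hypergeometric test of sequence-level hit counts in foreground vs
background sequence sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

PROB_FLOOR = 1e-4
DEFAULT_SCORE_FRACTION = 0.8

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position probability matrix (4 x L, rows A/C/G/T) with background."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A/C/G/T)")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @classmethod
    def from_counts(cls, name: str, counts, background=None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        return cls(name, probs, background)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        p = np.clip(self.matrix, PROB_FLOOR, None)
        return np.log2(p / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


def pwms_from_jaspar(motif_list) -> list[PWM]:
    """Convert Biopython JASPAR motifs into :class:`PWM` objects."""
    out = []
    for m in motif_list:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        out.append(PWM.from_counts(m.name or m.matrix_id, counts))
    return out


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq.upper()), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid sequence character {exc.args[0]!r}") from exc


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray, threshold: float) -> list[tuple[int, float]]:
    L = lo.shape[1]
    n = codes.size
    if n < L:
        return []
    hits = []
    # window score via per-column lookups; N (code 4) poisons the window
    scores = np.zeros(n - L + 1)
    valid = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        col = codes[j : j + n - L + 1]
        isn = col == 4
        valid &= ~isn
        scores += np.where(isn, 0.0, lo[np.minimum(col, 3), j])
    for off in np.flatnonzero(valid & (scores >= threshold)):
        hits.append((int(off), float(scores[off])))
    return hits


def scan_sequence(
    seq: str, pwm: PWM, score_fraction: float = DEFAULT_SCORE_FRACTION
) -> list[tuple[int, str, float]]:
    """Scan both strands; a hit scores >= score_fraction * max log-odds.

    Returns (offset on the forward sequence, strand, score) triples;
    windows containing N are skipped.
    """
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than the PWM")
    lo = pwm.log_odds()
    threshold = score_fraction * pwm.max_score()
    codes = _encode(seq)
    hits = [(off, "+", s) for off, s in _scan_one_strand(codes, lo, threshold)]
    rc = _encode(seq.upper().translate(_COMPLEMENT)[::-1])
    n = len(seq)
    for off, s in _scan_one_strand(rc, lo, threshold):
        hits.append((n - pwm.length - off, "-", s))
    return sorted(hits)


def _hit_count(seqs: dict[str, str], pwm: PWM, score_fraction: float) -> int:
    return sum(1 for s in seqs.values() if scan_sequence(s, pwm, score_fraction))


def motif_enrichment(
    foreground: dict[str, str],
    background: dict[str, str],
    pwms: list[PWM],
    score_fraction: float = DEFAULT_SCORE_FRACTION,
) -> pd.DataFrame:
    """Per-motif sequence-level enrichment of foreground over background.

    Counts sequences with >=1 hit in each set and tests enrichment with a
    one-sided hypergeometric tail over the pooled sequence universe;
    BH-adjusted across motifs.  The odds ratio uses a Haldane 0.5
    correction when any cell is zero.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be nonempty")
    n_fg, n_bg = len(foreground), len(background)
    rows = []
    for pwm in pwms:
        fg_hit = _hit_count(foreground, pwm, score_fraction)
        bg_hit = _hit_count(background, pwm, score_fraction)
        M = n_fg + n_bg
        K = fg_hit + bg_hit
        p = float(stats.hypergeom.sf(fg_hit - 1, M, K, n_fg))
        a, b = fg_hit, n_fg - fg_hit
        c, d = bg_hit, n_bg - bg_hit
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append((pwm.name, fg_hit, bg_hit, (a * d) / (b * c), p))
    table = pd.DataFrame(
        rows, columns=["motif", "fg_hits", "bg_hits", "odds_ratio", "pvalue"]
    ).set_index("motif")
    table["padj"] = adjust_bh(table["pvalue"].to_numpy())
    return table.sort_values("padj")
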