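# Methods

This note documents the statistical models, default parameters and design
choices behind `apoptosig`, and what the synthetic study does and does not
emulate.

## Differential expression

Counts for gene *g* in sample *j* are modelled as negative binomial with
mean `mu_gj = s_j * q_g * 2^(beta_g * x_j)` and variance `mu + alpha_g mu^2`
(`alpha_g` = dispersion). `x_j` indicates the treatment group; every
contrast is a two-group comparison of one treatment against the DMSO
control within one cell line. This replaces a full multi-line interaction
model: the contrast semantics (treatment vs DMSO within a line) are
identical, while estimation stays fully specified and auditable.

* **Size factors** — median-of-ratios on the linear ratio scale, with the
  geometric-mean reference restricted to genes nonzero in all samples;
  total-count fallback (geometric mean 1) with a logged warning when no
  such gene exists.
* **Dispersions** — per-gene method-of-moments estimates pooled within
  condition groups, then shrunk toward a parametric trend
  `alpha(mu) = a0 + a1/mu` fit by least squares on the untruncated
  estimates. Final estimate `(1-w)*max(alpha_hat,0) + w*trend`, floored at
  1e-8. The default weight is **w = 0.9**: with three replicates the
  gene-wise moment estimate has ~4 degrees of freedom and is noise-
  dominated; lighter shrinkage lets genes with underestimated dispersion
  inflate the Wald statistic and pushes the null rejection rate at p<0.05
  above its nominal level, while w = 0.9 keeps the empirical type-I error
  inside the 99% binomial band around 0.05 (measured on all-null
  simulations, 2000 genes, 3 vs 3). The weight is configurable for designs
  with more replicates.
* **GLM fit** — per-gene IRLS on the two-parameter log-link model with
  size factors as offsets, vectorised across genes; at most 50 iterations,
  convergence at max|Δβ| < 1e-8. Wald z = log2FC/SE with SE from the
  expected information; two-sided normal p; BH adjustment across tested
  genes. Genes all-zero in both groups are reported NA and excluded from
  the BH denominator; genes all-zero on one side get a sign-capped
  |log2FC| = 10 with NA p (the MLE diverges). No fold-change shrinkage or
  independent filtering is applied.

## Program-level analysis

Condition means of normalised counts (log2, +1 pseudocount) for the
combined significant genes are z-scored per row (sample SD, ddof=1;
constant rows map to zeros and are flagged), clustered with agglomerative
hierarchical clustering (Euclidean distance, complete linkage by default;
average/Ward available) and cut to exactly k groups (defaults: 5 and 7 for
the two default cell lines). The "double-high" selection rule is
formalised as: a group qualifies when its mean z in the TGFβ1+MEKi
condition is the maximum across conditions **and** positive; the selected
gene set is the union of qualifying groups. The heatmap-box selection this
replaces is inherently visual; the max-mean-z rule is the objective
rendering of "higher expression in the double treated samples".

**GSEA.** Genes are ranked by the log2 fold changes of significant genes
(padj < 0.05), descending, ties broken by symbol. The running score adds
`|metric|^p / sum_hits |metric|^p` at hits and subtracts `1/(N - N_hit)` at
misses; ES is the signed extremum; weight p = 1 by default. Significance
uses gene-label permutation (sample permutation is impossible on a
pre-ranked list): p = (1 + #{|null ES| ≥ |ES|}) / (1 + n_perm), two-sided
on |ES| so that p is uniform under a random gene set; NES divides ES by
the mean |null ES| of the same sign and is NA (with a warning) when no
null ES shares the sign. BH adjustment across gene sets. Note the classic
statistic is not invariant to padding the ranking with zero-metric
non-members: padding shrinks the per-miss decrement, so a positive ES can
only grow; the property tests assert this monotone behaviour.

## Treatment signatures and module scores

A gene joins a treatment's signature when it passes padj < 0.05 **and**
log2FC > 1 (one-sided, up-regulated only) in exactly that treatment;
signatures are pairwise disjoint by construction and carry per-member
provenance tags. Module scores re-implement the bin-matched control
scheme: genes are ranked by mean expression across cells (ties by symbol)
and split into `n_bins = 24` equal-size bins; each signature gene draws
`n_ctrl = 100` control genes from its bin (without replacement when the
bin allows, with replacement otherwise); score(cell) = mean signature
expression − mean pooled control expression. Defaults follow the common
convention of the original implementation; both are configurable. Scores
are invariant to global additive shifts and bitwise reproducible under a
fixed seed.

## Peak operations

All intervals are 0-based half-open (BED native). Replicate consensus is
the strictest reading of "called in both replicates": the base-pair
intersection of the two antibody replicates, merged to disjoint intervals.
Condition-unique regions come from a maximal partition of the genome by
membership bit-pattern; in the pipeline, unique regions narrower than 50 bp
are dropped before gene association — they are boundary slivers produced by
jittered replicate ends, not independent binding events. Feature annotation
classifies the peak midpoint with priority promoter-TSS (TSS ± 1000 bp) >
exonic > intronic > intergenic; the annotation table may carry optional
exon block columns (the synthetic annotation writes a two-exon structure),
without which gene-body hits outside the promoter window count as intronic.

Regulatory domains follow the basal-plus-extension defaults of the
peak-to-gene tool they stand in for: basal = TSS − 5000 … TSS + 1000
(strand-oriented), extended up to 1 Mb each side but stopping at the
nearest neighbouring gene's basal domain, clipped to chromosome bounds.
Neighbouring extended domains therefore overlap over shared intergenic
space, and a peak may associate with several genes. Scaled signal profiles
rescale each peak body to a fixed bin count by mean pooling, with flanks
of twice the peak width each side binned at the same percent resolution
(zero-padded outside the chromosome).

## Signature assembly

Symbols are uppercased and whitespace-stripped. The pro-apoptotic universe
is the apoptotic-process set minus the negative-regulation set (an optional
one-to-many ortholog table is applied first; unmapped symbols are dropped
with a logged count). The Venn partition over {line-A double DEGs, line-B
double DEGs, double-unique peak genes, apoptosis universe} produces all 15
exclusive membership patterns; the apoptosis signature is the union of the
four patterns of interest — the all-four core, lineB∩peaks∩universe
(excluding line A), lineA∩peaks∩universe (excluding line B) and
lineA∩lineB∩universe (excluding peaks) — with each member tagged by its
pattern. The patterns are exclusive Venn regions, not loose intersections.

The baseline marker screen compares log2(x+1) group means between
sensitive and resistant lines with a two-sided Welch t-test; a gene is
flagged when |Δ| strictly exceeds 0.3 and p < 0.05. The ±0.3 threshold is
interpreted on the log2 scale (configurable); the scale is recorded in the
output.

## Motif enrichment

PWMs are probability matrices (columns sum to 1, probabilities clipped to
≥ 1e-4 before log-odds against a uniform background). Both strands are
scanned; a window is a hit when its log-odds reaches `score_fraction = 0.8`
of the maximum attainable score; windows containing N are skipped.
Enrichment counts *sequences* with ≥ 1 hit (robust to peak-length
variation) and tests the foreground count with a one-sided hypergeometric
tail over the pooled sequence universe, BH-adjusted across motifs; odds
ratios use a Haldane 0.5 correction at zero cells.

## Dose–response

The 4PL model is `r = bottom + (top − bottom)/(1 + 10^(hill (log10 d −
log10 IC50)))`, fit by bounded least squares (trust-region reflective) with
5 jittered restarts keeping the best residual sum of squares; the IC50
search range is the tested dose range extended one decade each side.
Vehicle rows (dose 0) are anchored at log10 = −5 on the micromolar scale,
the convention used for control wells; the anchor is configurable. A fit
is **flat** — IC50 undefined — when the fitted amplitude |top − bottom| is
below `flat_fraction = 0.2` of the mean vehicle response, or when the hill
slope's 95% CI (Gauss–Newton covariance) reaches zero. The amplitude rule
is stated against baseline viability rather than the replicate spread of
the vehicle wells, which is pure noise scale and would never trigger on
clean data. Two classification rules are provided and never mixed: the
absolute threshold (sensitive iff IC50 strictly below 2000 pM; undefined
IC50 is resistant) and the ranking rule (resistant = the n highest IC50s
plus every undefined line; sensitive = the n lowest; middle unclassified;
ties broken by line name).

## Synthetic study

The default `TruthSpec` emulates the study conditions: 2000 genes, two
cell lines × four treatments (DMSO, TGFB1, MEKI, TGFB1_MEKI) × three
replicates; NB counts (`variance = mu + alpha mu^2`, alpha = 0.05,
baselines log-uniform in [20, 2000], library sizes log-uniform in
[0.7, 1.4]) with three implanted 60-gene blocks — pro-invasive (log2FC +2
under TGFβ1, −1 under the double treatment), pro-apoptotic switch (+3 in
the double treatment only) and MITF-like (+1.5 under MEKi). Peaks: 100
shared loci plus condition-unique loci within 15 kb of each target-block
TSS; 85% of a condition's peaks appear in both antibody replicates with
endpoints jittered by at most ⌊width/4⌋ (guaranteeing ≥ width/2 overlap),
the rest in one replicate. Foreground sequences implant the SMAD-binding-
element consensus at rate 0.8; backgrounds are per-sequence dinucleotide
shuffles (Eulerian-walk, preserving the dinucleotide multiset). Single
cells are log-normal with state-specific block shifts (+1.0): NCSC over-
expresses the switch block, invasive the invasive block, pigmented the
MITF block. Dose–response curves use six lines spanning IC50 0.5–100 nM
plus two flat resistant lines, 2% Gaussian noise, doses 16 pM–262 nM
(4-fold series). All randomness derives from one root seed through fixed
`SeedSequence` spawn keys (annotation 0, counts 1, peaks 2, sequences 3,
single cell 4, dose–response 5, gene sets 6).

**What the generator does not emulate**: batch effects, gene–gene
correlation, dropout/doublets in the single-cell matrix, GC or
mappability bias in peaks, heavy-tailed count outliers, and real gene
identities. Passing tests therefore demonstrate correctness of the
computational route and its calibration under the stated model, not
robustness to every artefact of real sequencing data.

## Problem sizes and numerics

Default analyses run on 2000-gene fixtures with 3 replicates per
condition, 200-simulation calibration batches, 200–999 permutations for
GSEA and 100-trial oracle batches — sizes at which every documented check
completes in well under a minute on a single CPU while keeping binomial
bands meaningful. Degenerate inputs are handled explicitly: constant genes
floor at the dispersion minimum, constant z-rows flag and zero, empty
signature assemblies return None with a warning, unmapped peaks are
recorded as unassigned, and non-converged fits carry NA statistics rather
than silent numbers.
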