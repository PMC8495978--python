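# Methods

This note documents the models and procedures implemented in `splitlr`,
the parameters that matter, the numerical conventions, and what the
synthetic data do and do not establish.

## Demultiplexing model

A barcoded long read is modeled, on its forward (cDNA-first) strand, as

```
cDNA | UMI | bc3 | linker1 | bc2 | linker2 | bc1
```

where `bc_i` is the round-*i* well barcode and the linkers are the fixed
spacer sequences between barcoding rounds. Round 1 encodes priming: each
physical well contains an oligo-dT and a random-hexamer primer with
distinct barcodes, so two round-1 barcodes map onto one well.

**Linker location.** Each linker is aligned semi-globally (edlib, infix
mode) inside a search window inferred from the layout geometry anchored at
the 3' read end, padded by ±10 bp plus the error budget. A placement is
accepted with at most `max_linker_errors` (default 2) edits per linker;
both orientations are tried and the lower total edit distance wins (ties
go to forward). Failure of either linker, or overlapping/out-of-order
placements, classifies the read `NO_LINKERS`.

**Barcode correction.** The nominal barcode windows are the fixed-length
segments flanking the linker hits (truncated windows at the read boundary
are tolerated up to the edit budget, since a terminal deletion shortens
the read). Correction accepts the unique whitelist entry at minimum
Levenshtein distance when that minimum is ≤ `max_edit_distance` (default
3); ties are rejected as `AMBIGUOUS` rather than resolved arbitrarily —
determinism over yield. Full Levenshtein (substitutions + indels) is used
because indels dominate long-read error profiles. In the demultiplexing
path the correction is evaluated semi-globally against a window padded by
the edit budget: linker alignments can end a base or two off when errors
fall on their boundaries, and infix scoring is invariant to such shifts
while never reporting a larger distance than the fixed window would. The
standalone `correct_barcode` operation implements the plain
fixed-string contract and is validated against a brute-force DP oracle.

**Cell assembly.** Corrected triples may be filtered against the barcode
combinations observed in companion short-read data (any user-supplied
list; the filter is optional). The round-1 barcode is then replaced by its
well id, merging the dT/hexamer pair into one cell while the per-read
priming label is kept for stratified analyses. UMIs are recorded verbatim
with no error correction; counts are reads, not UMIs, by default.

## End calling

Reads are first filtered by transcript novelty: 5' ends are trusted only
for classes that preserve the annotated 5' region (known, NIC, NNC,
prefix-ISM), 3' ends for classes preserving the 3' region (known, NIC,
NNC, suffix-ISM). Genomic, antisense, intergenic and other-ISM reads are
excluded. No per-position expression pre-filter is applied.

Distinct end positions per (chromosome, strand) are chained left to right
into clusters wherever the gap between consecutive positions is ≤ the
window size (default 50 bp). Per cluster: the summit is the position with
the highest read count, ties resolved to the 5'-most base in transcript
orientation; the wide peak spans the cluster; the narrow peak is the
summit ± half window clipped to the wide peak. Coordinates are 0-based
half-open throughout. This chaining rule, the tie-break and the narrow
definition are this package's own explicit conventions (the window size
and support thresholds are the domain-standard ones); the caller is
validated against an exhaustive clustering oracle.

Clusters need ≥ `min_reads` support (2 for long reads, 20 for short-read
mode). Each peak takes the majority gene of its supporting reads (ties:
larger genome-wide read total, then lexicographic). Within a gene whose
strongest peak has M reads, a peak is kept iff its count is **strictly**
greater than `gene_fraction · M` (10% single-cell TSS, 5% bulk TSS, 80%
TES — applied to both bulk and single-cell TES calls); the strongest peak
is always kept. Peaks are named `<gene>_<k>` by ascending summit
coordinate — the numbering convention is coordinate order, chosen for
determinism. Short-read mode applies no gene-fraction filter.

Short-read end selection mirrors the adapter-based heuristics: a 5'-end
read must contain the complete template-switching oligo with zero errors
(internal occurrence allowed); a 3'-end read must contain a 20-bp window
with ≥ 10 adenines. Validation intersects peak wide extents with external
interval sets at ≥ 1 bp overlap (strand-blind, since validation sets are
typically unstranded region calls); assembly mismatches between peak and
validation coordinates are undetectable and the caller's responsibility.

## TSS quantification

Each read start is expanded to `[start − 25, start + 25]` (clipped at 0)
and assigned to a TSS peak when the expanded interval overlaps the peak's
wide extent by ≥ 1 bp on the same chromosome and strand. By default the
read's gene must also match the peak's gene — a guard against cross-gene
bleed at overlapping loci that plain positional intersection lacks; it
can be disabled (`gene_gate=False`). A read overlapping several candidate
peaks goes to the peak containing its unexpanded start, else the nearest
one, ties upstream. Assignment is conservative: per cell, assigned +
unassigned equals the input read count.

Filters follow fixed boundary conventions, all table-tested: cells need
≥ 500 reads (inclusive); single-cell novel transcripts need detection in
≥ 4 cells (known transcripts exempt); bulk novel transcripts need ≥ 5
copies in ≥ 2 replicates and, when genomic-A metadata exists, an A
fraction ≤ 0.5.

## Differential usage test

For two cell groups, reads are pooled per group ("counts in each
condition" is read as pooling, not averaging). Per gene, features are
ranked by total count (ties lexicographic); beyond 11 features the
lowest-ranked are pooled into an "other" row, so the table is at most
11 × 2. A gene is testable with ≥ 10 reads in each column and ≥ 2
non-empty rows. The Pearson statistic Σ(O−E)²/E with marginal-derived
expectations, df = rows − 1, no continuity correction (n × 2 with n ≥ 2),
rows empty in both conditions dropped first. Δπ is the sum over the two
most-expressed features of |π_A − π_B| where π is percent usage; the
pooled row is eligible for the top-two by default (configurable), as its
usage change is as real as any feature's. BH correction is applied per
pairwise comparison over testable genes only. Significance: adjusted
p ≤ 0.05 and Δπ ≥ 10.

Calibration: with 5 equally used isoforms and 50 reads per group (expected
cell counts ≈ 10) the pre-correction rejection rate at α = 0.05 sits
inside the exact binomial 99% interval on 2,000 null genes; power for a
two-isoform 80/20 → 20/80 flip (Δπ = 120) at 100 reads/group is ≈ 1.

## Accessibility integration

Expression and accessibility matrices over the same TSS set are averaged
per group; fold changes use log2((a + 1)/(b + 1)) — the pseudocount keeps
LFCs finite and maps (0, 0) to 0, and the transform is antisymmetric in
its arguments. Specificity thresholds are k·SD (default k = 2, sample SD
over all TSSs of the comparison, including non-specific ones); a TSS is
group-specific only when both modalities exceed the threshold in the same
direction. Binary states use inclusive cutoffs (≥ 2 reads expressed,
≥ 1000 normalized accessibility accessible); inclusivity at the boundary
is this package's choice. Top-TSS concordance restricts to genes with > 1
TSS and counts a gene concordant when the argmax sets of the two
modalities intersect. Accessibility normalization is upstream and out of
scope; the module is normalization-agnostic.

## Synthetic data

The generators are pure functions of their configuration and seed
(bit-identical on repeat). Defaults encode the study conditions used
throughout the tests: barcode substitution rate 0.01 and indel rate 0.002
per base; read-end jitter Normal(0, 5 bp) rounded to integers; TSS
architectures of 1–4 sites ≥ 200 bp apart with 50–500 reads per gene;
null usage uniform over 5 isoforms at 50 reads per condition; planted
switches specified as per-condition usage vectors.

Synthetic whitelists default to 16-bp barcodes at minimum pairwise
Levenshtein distance ≥ 7 (48 per round), which makes distance-3 correction
provably unambiguous — a deliberate idealization: real kits use 8-bp
barcodes whose whitelists cannot reach that separation, so real-data
correction can be ambiguous where the synthetic round-trip cannot. A
"hard mode" (distance-4 whitelists) exercises the ambiguous path. Linker
sequences are fixed synthetic constants of realistic lengths (30 and
22 bp). Accessibility is coupled to expression as
`acc = baseline + sign(r)·(expr − mean) + noise` with the noise variance
solved for the target Pearson r; truncation at zero is negligible at the
default baseline (1000) but biases extreme-spread configurations.

What passing on these data does **not** show: robustness to structured
long-read errors (homopolymer compression, chimeras), to mis-annotated
novelty labels, to non-Gaussian end noise (e.g. internal priming creating
false TES pileups — the reason TES calls use the stringent 80% gene
fraction), or to ambient/doublet contamination in real cells.

## Problem sizes and determinism

The verification suite runs everything at desk scale: 10,000 reads for the
demultiplexing round trip, 20 genes / ~50 planted TSSs for end-calling
recovery, 2,000 null genes for calibration, 2,000 TSSs for correlation
recovery, and a 500-read end-to-end pipeline executed twice to confirm
byte-identical outputs. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; the pipeline manifest records stage
parameters and SHA-256 content checksums of every output.

## Known limitations

- The end caller's chaining is greedy left-to-right; two genuine sites
  < 50 bp apart merge into one peak by construction.
- UMI handling is exact-match only and off by default; sequencing errors
  in UMIs inflate molecule counts in UMI mode.
- The usage test treats cells of a group as exchangeable (pooled counts);
  it does not model per-cell overdispersion, so p-values on strongly
  clumped data are anti-conservative.
- Validation intersection cannot detect assembly mismatches between peak
  and validation coordinates.
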