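# Methods

## Data model

A *poly(A)-site* (PAS) is the single genomic nucleotide at the junction
between a transcript's 3'UTR and its poly(A) tract, evidenced by the 3'
ends of mRNA-sense aligned reads. A *poly(A)-cluster* (PAC) is a genomic
interval grouping one or more sites lying within a merge window of each
other; clusters are the unit of annotation, counting and testing.
Coordinates are 0-based half-open everywhere internally and in BED/bedGraph
output; 1-based coordinates appear only inside human-readable cluster
names, matching genome-browser display.

## Preprocessing

Reads are oriented to mRNA sense first (protocols that leave a poly(T)
tract at the 5' end are reverse-complemented, controlled by
`reverse_complement`). Generic adapter/quality handling is reduced to two
steps — drop the first `leading_trim` bases (default 6) and discard reads
with mean Phred quality below `min_mean_quality` (default 20) — because
that work belongs to dedicated trimmers; only the poly(A)-specific logic
is this package's concern.

Tail removal is a deterministic 3'-anchored scan rather than an
adapter-matching heuristic: the maximal terminal A-run is consumed,
allowing at most one non-A interruption per `tail_interruption_every`
consecutive A's (default 10; 0 disables tolerance), and an interruption is
never the junction-proximal base of the tract. Anchoring at the 3' end
cannot clip A-runs in the middle of a read, and the scan is trivially
invertible for testing: the measured tail length always equals the length
difference of the read. Reads keep less than `min_tail_in_read` = 10
removed A's, or fewer than `min_read_len` = 40 remaining nucleotides, are
discarded. The tail length is appended to the read id as `:<n>A` (after
stripping any whitespace comment) so it survives the SAM QNAME round trip.

## Site calling and internal-priming masking

Alignments of all samples are pooled before site calling: a site seen by
two reads in each of three samples is as real as one seen by six reads in
one sample, and pooling maximizes discovery power. The 3' end of a
forward alignment is its rightmost aligned reference base; of a reverse
alignment, its leftmost (reads are mRNA-sense, so alignment strand equals
transcript strand). Soft clips are excluded; secondary/supplementary and
duplicate-QNAME records are skipped (first primary wins).

A read *qualifies* when its measured tail has at least `pas_min_tail` = 25
A's — more than the 21-nt unanchored oligo-dT primer can contribute, so
the tail cannot be pure primer. Sites need `pas_min_reads` = 5 qualified
reads; unqualified reads still accumulate in `total_reads` for
diagnostics, since protocols retaining only 10-15 tail nucleotides must
lower these thresholds. Finally a site is masked as a likely internal
oligo-dT priming artifact when the `ip_window` = 20 genomic nucleotides
immediately downstream (transcript sense: forward sequence for '+',
reverse-complemented upstream window for '-') contain at least
`ip_max_A` = 12 A's. Masked sites are excluded from everything downstream
but written to a diagnostics bedGraph.

## Clustering

Unmasked sites of one chromosome and strand are merged by single-linkage
chaining: successive sites with positional gap ≤ `cluster_window` = 25 nt
join one cluster, transitively, so a dense chain may span more than one
window. This is the simplest deterministic reading; no cap is applied to
total cluster width. Opposite-strand sites never merge. Each cluster
records the modal member (most qualified reads, ties to the lower
coordinate — determinism over biology, since ties are rare and arbitrary)
which BED output marks via the thick columns.

## Annotation and naming

Clusters are annotated against strand-labelled exon and intron BED
intervals (gene in the name column; a GTF converter utility is provided).
Category priority is exon > intron > downstream-of-terminal-exon >
intergenic, with ≥ 1 shared same-strand base for overlap and
`downstream_window` = 250 nt measured from the terminal exon's 3' end.
When a cluster overlaps exons of several genes, the gene whose *terminal*
exon it overlaps wins (sites biologically belong to transcript ends), then
the longer overlap, then the lexicographically first gene.

Names follow `{gene}_{category}_{chrom}:{feature_start_1based}_PAS-{k}`
with ordinals assigned 5'→3' along the transcript (ascending genomic
coordinate on '+', descending on '-') within each host feature, so
`PAS-1` is always the most proximal cluster and APA direction becomes a
pure ordinal comparison. Intergenic clusters are `intergenic_PAS-{k}`,
numbered in (chrom, start) order genome-wide. Naming is idempotent, and
externally supplied cluster databases (any BED6+) are sorted, converted
(representative = interval midpoint when thick columns are absent) and
named identically, so downstream stages cannot tell the difference.

## Counting and collapsing

A read is counted for a cluster when its 3' end lies inside the cluster
span or within `count_window` = 10 nt of it on the same strand; each read
goes to at most one cluster, with equidistant ties broken toward the
upstream (5'-ward) cluster — this keeps tables integer and prevents
double counting. By default counting applies the same qualified-tail
criterion as discovery (`min_tail` = 25, settable to `None`), keeping
quantification consistent with the evidence used to build the database;
both assigned and below-threshold totals are reported.

Exon-level tables sum cluster rows sharing a host feature; gene-level
tables sum exonic plus downstream-of-terminal-exon rows per gene, adding
intronic rows only when `include_introns` is set (intron-resident repeats
can inflate gene totals; an optional repeat BED drops overlapping clusters
before any summing). Intergenic clusters never collapse — they surface
only in cluster-level results. Collapsing is associative
(pac→exon→gene ≡ pac→gene) and conserves per-sample totals over the
retained categories.

## Differential testing

The engine is a deliberately simple, fully specified gamma-Poisson
pipeline; a backend hook accepts an external implementation wholesale.

* **Size factors.** Median-of-ratios over features expressed in every
  sample, rescaled to geometric mean 1; library-size fallback (with a
  warning) when no feature qualifies.
* **Dispersion.** Method of moments on normalized counts,
  `α̂ = max(0, (v − m·mean(1/s_j))/m²)`, using the pooled *within-group*
  residual variance `v` (df = n − 2) so a real condition effect is not
  booked as overdispersion. Estimates are shrunk toward a running-median
  trend over log mean with weight `shrinkage_weight` = 0.7 (window = 5% of
  features, min 25). Because `v` is roughly `σ²·χ²_df/df` and the trend is
  a median, the variance entering the trend is divided by the χ² median
  factor `χ²_df(0.5)/df` (≈ 0.84 at df 4); without this the trend
  underestimates dispersion by ~16% at n = 3 per group and inflates
  type-I error. All-zero features are excluded and reported NA.
* **Wald test.** Per-condition NB means are fitted by Newton iterations
  on the log scale with size-factor offsets and the shrunk dispersion;
  `log2FC = log2(μ_B/μ_A)` with standard error from the expected Fisher
  information. When one condition is entirely zero the normalized mean is
  floored at `pseudo_mean` = 0.5 and the row flagged. P-values use a
  moderated-t reference with df = d + d·w/(1−w) (d = residual df,
  w = shrinkage weight; w→1 recovers the normal): the shrinkage acts as
  prior degrees of freedom, and the plain normal reference is visibly
  anticonservative in the tails at n = 3.
* **FDR.** Benjamini–Hochberg by default; `weighted_bh` stratifies
  features into 5 quantile bins of base mean, estimates each bin's
  non-null fraction (Storey, λ = 0.5), converts to mean-1 hypothesis
  weights and applies BH to `p/w` — an independent-hypothesis-weighting
  style procedure that reduces exactly to BH under uniform weights.

Measured on null NB simulations (10,000 features, n = 3 + 3, dispersion
0.05), the rejection rate at p < 0.05 sits near 0.035 and programmed
4-fold effects on a 5% feature subset are recovered with mean log2FC ≈
1.96 (these numbers are recomputed by the test suite, not asserted as
constants beyond their tolerance bands). Multiplying one sample's column
by a constant is absorbed by its size factor *approximately*, not
exactly: any likelihood fit re-weights the deeper sample slightly (capped
by the dispersion), so the invariance test asserts closeness, not
equality.

## Classification

Occupancy of a cluster in a condition is its mean normalized count over
that condition's samples divided by the gene total over the gene's
clusters (size factors from the cluster table; condition means give
comparability across samples). A cluster is *eligible* at
`min_occupancy` = 0.05 in at least one condition; genes silent in one
condition get NA occupancies there and are judged on the other.

DGE is UP/DOWN at |log2FC| > log2(1.5) and padj < 0.1 on the gene table,
else NC. A *triggering* cluster is eligible, has cluster-level padj < 0.1
and moves occupancy by at least `min_frac_change` = 0.10 — read as
absolute percentage points, the standard APA convention, since a relative
reading explodes for small occupancies. A triggering cluster paired with
an eligible cluster in another feature gives TE; within one feature the
direction comes from ordinal position (proximal gaining usage ⇒
shortening, distal gaining ⇒ lengthening; a triggering middle cluster
with opposite-signed shifts on at least one flank per side ⇒ "both";
opposite shortening+lengthening votes also collapse to "both"). TE and
APA can co-occur. The compiled report has one gene row per tested gene
and per-cluster sub-rows for multi-cluster genes (intronic clusters only
when intron inclusion was requested), in deterministic order.

## Synthetic studies

The generator emulates the assumed data geometry: reads whose 3' ends sit
exactly at planted sites (± a jitter parameter, default 0), tails of
25-40 A's, per-site read numbers drawn NB(mean, dispersion) per sample,
two conditions × 3 replicates, dispersion 0.05. Genomes are uniform
random sequence with every planted site's downstream window overwritten —
A-free for genuine sites, 16 A's for decoys — so the masking rule has
exact known truth. Reads are emitted both as FASTQ (for the
preprocessing path, including a poly(T) mode) and as coordinate-sorted
SAM with the tail already in the QNAME, so the pipeline is testable
without an aligner; an integration test exercises the FASTQ→aligner path
with minimap2.

The 200-gene classifier study plants 40-point occupancy swaps
(shortening/lengthening), terminal-exon switches, and 4-fold expression
changes in a *sparse* regime (25% of genes carry any effect, as in real
knockdown studies where APA touches a minority of genes); gene totals are
lognormal around 400. Mirroring flips every gene's strand after drawing
counts, so ordinals reverse on byte-identical tables — a pure
strand-symmetry probe of the classifier.

What the simulations do **not** emulate: sequencing errors and quality
variation (constant Q40), spliced alignments (reads stay within one
exon), mappability/multimapping, 3'-end heterogeneity beyond the jitter
parameter, library-composition biases, and paired-end or UMI structure.
Passing tests therefore certify the pipeline's logic and statistics, not
robustness to alignment artifacts in real data.

## Numerical and degenerate-input choices

Newton fits run at most 50 damped iterations from the ratio-estimator
start and are clipped to ±5 per step; dispersion is floored at 1e-8 in
the fit. Empty FASTQ/SAM inputs yield empty-but-valid outputs; windows
running off chromosome ends are truncated; an empty cluster database is
an error at counting; a gene present at cluster level but missing from
the gene table is a consistency error. Ties are broken deterministically
everywhere (documented per stage above), and all generators are seeded —
equal seeds give byte-identical FASTA/FASTQ/SAM/CSV outputs.

## Problem sizes used in the checks

The reference checks run at desk scale: a ≤ 35-kb two-chromosome toy
genome with seven genes for end-to-end identity and conservation; 1,000
random layouts for the clustering oracle; a 10-kb genome, every position
and both strands, for the masking oracle; 10,000 features for engine
calibration; 200 genes for classifier recovery. These sizes give the
statistical assertions comfortable margins while keeping the whole suite
fast.

## Known limitations

Two-condition, unpaired designs only; no likelihood-ratio tests or
log2FC shrinkage estimators; no transcript-isoform-resolved annotation or
UTR boundary refinement; no multimapper rescue; single-end reads; the
simplified NB engine approximates, but is not, the canonical heavyweight
pipelines (hence the backend hook).
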