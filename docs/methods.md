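# Methods

## Background and scope

MeD-seq reads out DNA methylation with the methylation-dependent
restriction enzyme LpnPI, which cleaves only at methylated CpG-containing
recognition sites and excises ~32-bp fragments around them. After
single-end 50-bp sequencing, the number of reads assigned to a recognition
site is a direct measure of that site's methylation. This package
implements the full downstream analysis — site cataloguing, read
processing, region aggregation, two flavors of differentially methylated
region (DMR) detection, hierarchical clustering — together with the
heuristic somatic-variant filter and the parental-line → iPSC-clone
mutation-inheritance comparison used alongside the methylation analysis,
and a synthetic-data generator so every stage is testable end to end
without any external download.

Upstream wet-lab and heavy informatics steps are out of scope: alignment
of real human data (real alignments enter via SAM import), variant calling
and annotation (annotated variant tables are inputs), and gene-ontology
enrichment.

## The digestion and read model

A recognition-site catalog is built by scanning both strands of the
genome for the enzyme motif (default `CCDG`, the published LpnPI
specificity; configurable) and keeping instances that contain a CG
dinucleotide. The read-out coordinate of a site is the + strand position of
the C of the leftmost CG in the instance; instances on the two strands that
share this coordinate (e.g. the palindromic `CCGG`) are merged into one
catalog entry, because counts are keyed by read-out position.

The simulator draws, for each site, a fragment count from
Binomial(depth, methylation probability), where `depth` is the expected
count at a fully methylated site. Each fragment is exactly 32 bp of genomic
sequence with the site's CpG cytosine at fragment offset 15 or 16 (chosen
uniformly); since only the fragment length and the downstream 13–17 bp
filter window are fixed by the assay, this near-central placement is the
one geometry consistent with both. Fragments are emitted in forward or
reverse-complement orientation with equal probability (single-read
libraries sequence either strand) and padded 3′ with adapter sequence to
the 50-bp read length, emulating sequencing through a short insert.

A faster count-level generator draws per-replicate site counts
multinomially with weights proportional to methylation probabilities —
this mirrors the fixed-library-size character of real sequencing and is
the workhorse for statistical tests.

### The toy genome

Background sequence is i.i.d. with a configurable GC fraction, then
CpG-depleted: by default 85% of background CG dinucleotides are mutated
away, reflecting the CpG underrepresentation of vertebrate genomes.
Without depletion, uniform random sequence is already CpG-rich and islands
cannot be meaningfully enriched. CpG islands overwrite their interval with
a generator that emits a `CCGG` block with the island's density parameter,
so islands are simultaneously CpG-enriched (≥3× background) and rich in
usable LpnPI sites.

What the generator does **not** emulate: sequencing errors, PCR
duplicates, mappability structure and repeats, bisulfite chemistry,
partial digestion, and realistic covariance between neighboring sites.
Replicate noise is additive Gaussian on methylation probabilities (sd
0.02 by default), clipped to [0,1] — a simple stand-in chosen because the
assay's replicate-level biological variance is not characterized; it is
exposed as configuration. Passing tests therefore demonstrate
correctness of the pipeline's logic and statistics under a clean
generative model, not robustness to real-data artifacts.

## Read processing

1. **Adapter trimming** removes the longest read suffix exactly matching
   a prefix of the adapter (≥5 bp); reads shorter than 20 bp afterwards
   are dropped and counted.
2. **Host-read removal** (optional, for lines cultured on feeder cells of
   another species) removes reads with an exact match in the host genome
   and none in the target; reads matching both are retained.
3. **Positional site filter**: a read passes iff it carries a motif
   instance whose CpG anchor lies 13–17 bp (inclusive, 0-based) from
   either read end — the geometric signature of LpnPI cleavage. The
   anchor is the CG's first base by default; filtering a
   reverse-complemented read with the mirrored anchor (the CG's second
   base) reproduces the original decision exactly, which is the form in
   which strand symmetry holds for a dinucleotide anchor.
4. **Mapping**: a seed-and-verify exact full-length matcher (16-mer seed
   index, both strands) designed for error-free toy genomes; real data
   enter as SAM/BAM via pysam, with secondary/supplementary records
   flagged multi-mapped.
5. **Site scoring**: each read contributes one count to the catalog site
   whose position falls inside the placement 13–17 bp from either end;
   among several candidates the site nearest the placement midpoint wins
   (lower coordinate on ties), and a multi-mapped read is counted once, at
   its lowest-coordinate placement with an assignable site. Unassignable
   reads are tallied by reason, and accounting is conserved at every
   stage: assigned + rejected = input.

## Regions and aggregation

Per the assay's annotation scheme, each gene contributes a TSS window
(1 kb before through 1 kb after the transcription start, in transcription
orientation) and a gene body (1 kb after the TSS to the transcription
end); CpG island intervals are taken verbatim. A gene body shorter than
the 1-kb window (gene < 2 kb) is dropped. A region's score per sample is
the sum of counts at catalog sites inside it; overlapping regions share
sites. Counts are normalized to reads per million (RPM) for fold changes;
group pooling sums raw counts and library sizes. Fold changes are
computed on pooled RPM values with a pseudocount of 1 on both sides, which
bounds zero-count folds and makes the "twofold" gate meaningful across
libraries of unequal size.

## DMR detection

Both callers use the Pearson chi-squared test (1 df, no continuity
correction — appropriate for the large counts of pooled MeD-seq libraries;
the degenerate all-zero margin returns p = 1) on the 2×2 table
[count, library − count] × [group A, group B].

**Region caller.** One test per annotated region; p-values corrected
within each region class (Bonferroni or Benjamini–Hochberg, default BH);
a region is a DMR iff q < α (default 0.05) and its pseudocounted RPM fold
change is *strictly greater* than 2 (the "more than twofold" selection).

**Sliding-window caller.** Every catalog site is tested genome-wide
(BH-corrected across all sites by default; raw α available since the
window-stage control is not prescribed). Maximal runs of consecutive
significant sites with concordant direction are binned — a non-significant
site or a direction flip breaks the run — and a bin is reported iff it has
≥10 LpnPI sites, spans ≥100 bp (first to last site + 1) and shows ≥two- or
fivefold change (thresholds phrased as minima are non-strict, unlike the
region gate).

**Three-group uniqueness.** With exactly three groups, each group is
tested one-vs-rest (the other two pooled); a DMR is unique to a group iff
its interval overlaps (≥1 bp) no DMR from the other two comparisons. A
practical consequence of one-vs-rest pooling: a single-group signal of
fold f appears diluted at fold ≈ (f+1)/2 in the other comparisons, so
signals above ~threefold are called in every comparison and excluded from
all unique sets. Unique-DMR analysis therefore highlights moderately
group-specific regions; this is inherent to the overlap-exclusion
definition and is deliberately not "corrected".

Threshold monotonicity holds throughout: raising any threshold never
increases the number of reported DMRs.

## Clustering and reporting

DMR count matrices are row-wise Z-scored with the population SD; constant
rows become all-zero (kept, flagged) so heatmap dimensions are stable.
Samples are clustered on city-block distances between Z-score columns with
complete linkage; columns are sorted lexicographically first so
agglomeration ties break deterministically. Dendrograms are exported as
Newick with ultrametric branch lengths (a node merged at height h sits at
depth h/2), so two samples at distance d yield `(A:d/2,B:d/2);`.
Per-locus tracks (bedGraph/TSV, per-sample or group-mean) cover any
interval of the catalog.

## Variant filtering and inheritance

The heuristic post-calling filter keeps a call iff all caller filters
pass, total depth ≥ 6 reads, and population (ExAC) allele frequency
≤ 0.02% (0.0002 as a fraction; the constant is a single configurable
value in case the percent scale was intended differently). A missing
population frequency means a novel variant and is treated as 0 — novelty
never causes rejection. Rejections are tallied by the first failing rule
in the order caller filter, depth, population AF. Variant identity is an
exact (contig, pos, ref, alt) match; inputs are assumed normalized
upstream.

The inheritance comparison takes the filtered somatic variants of each
parental line, looks them up in every derived clone (lineage map), and
classifies each variant as present in **all**, **some** or **none** of
the clones; the classes partition the rows, and absence is encoded
distinctly from VAF 0.

## Problem sizes and numerical choices

Study conditions used by the test suite and the acceptance script, chosen
as desk-scale analogues of the assay:

* planted-DMR recovery: 1000 regions × 10 sites, 50 planted DMRs (25
  hypermethylated per group, so total weight is balanced and the realized
  RPM fold equals the nominal fivefold), 10⁶ reads per pooled group, BH at
  0.05 — sensitivity ≥0.95, observed FDR ≤0.05;
* null error control: 100 regions, 10⁵ reads/group, 200 replicate
  simulations, Bonferroni at 0.05;
* end-to-end round trip: one 250-kb contig (~300 LpnPI sites after
  depletion), per-site depth set to emit ~10⁵ reads; with error-free
  reads and unique mapping the recovered per-site counts equal the
  simulation truth exactly;
* probes: thresholds are recovered empirically (offset scans, bisection
  on fold, grids on depth/population AF) rather than read from
  configuration, so a regression in any gate is caught as a changed
  measured value.

Degenerate inputs are defined rather than rejected wherever a convention
is defensible: empty genomes give empty catalogs, site-less regions score
0 and are flagged, constant Z-rows are zeroed, and the degenerate
chi-squared table returns p = 1.

## Known limitations

* The exact matcher tolerates no mismatches; real data must be aligned
  externally and imported as SAM/BAM.
* The recognition motif is a parameter with a documented default; the
  package does not model MspJI digestion or enzyme kinetics.
* Fold-change gating interacts with fixed-library normalization: a
  differential region that carries a large fraction of total library
  weight has its RPM fold compressed (compositional effect), which is
  faithful to read-count data but means per-site methylation differences
  do not translate 1:1 into RPM folds.
* The FASTQ simulator and pipeline are pure Python and intended for
  toy-genome scale (≲10⁶ reads, ≲1 Mb genomes).
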