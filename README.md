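# medseq

Methylation profiling with methylation-dependent restriction-enzyme
sequencing (MeD-seq), for studying epigenetic memory in reprogrammed
cells: the enzyme LpnPI cuts only at methylated CpG-containing
recognition sites and releases ~32-bp fragments, so the read count at a
site measures its methylation. The package implements the complete
downstream analysis — recognition-site cataloguing, read processing with
the positional site filter, aggregation over TSS windows / gene bodies /
CpG islands, chi-squared and sliding-window DMR calling with two- and
three-group designs, Z-score hierarchical clustering — plus the heuristic
somatic-variant filter and the parental-line → iPSC-clone
mutation-inheritance comparison, and a synthetic-data generator that makes
every stage testable without any download.

It is aimed at analysts working with MeD-seq count data (or wanting a
fully specified, reproducible reference implementation of this kind of
pipeline) at desk scale: toy genomes, simulated reads, and externally
aligned real data via SAM import.

## The statistics in brief

For a region (or single site) with pooled counts $k_A, k_B$ in groups
with library sizes $N_A, N_B$, differential methylation is tested with
the Pearson chi-squared statistic (1 df, no continuity correction) on

$$\begin{pmatrix} k_A & N_A-k_A \\ k_B & N_B-k_B \end{pmatrix},$$

corrected per region class by Bonferroni or Benjamini–Hochberg. Effect
size is the pseudocounted RPM ratio
$\mathrm{FC} = (10^6 k_A/N_A + 1)\,/\,(10^6 k_B/N_B + 1)$. A region DMR
requires $q < 0.05$ and more than twofold change; a sliding-window DMR is
a maximal run of consecutive individually significant sites with
concordant direction containing ≥10 LpnPI sites, spanning ≥100 bp, with
≥two- (or five-) fold change. Clustering uses row-wise Z-scores,
city-block distance and complete linkage. The variant filter keeps calls
with all caller filters passed, depth ≥6 reads and population allele
frequency ≤0.02%.

See `docs/methods.md` for the full model, parameter table and known
limitations.

## Worked example

The numbered scripts under `analysis/` run a complete simulated study of
three predetermined groups — tubular epithelial cells (TEC), iPSC clones
derived from them (iPS), and embryonic stem cells (ES) — with two planted
"epigenetic memory" islands (methylated in TEC and iPS, not ES) and one
TEC-only island erased by reprogramming:

```bash
python analysis/01_simulate_study.py     # genome, methylome, FASTQs
python analysis/02_process_reads.py      # trim, filter, map, score
python analysis/03_call_dmrs.py          # region + window + unique DMRs
python analysis/04_cluster_samples.py    # Z-score complete/city-block tree
python analysis/05_variant_inheritance.py
```

`03_call_dmrs.py` prints (abridged):

```
iPS vs ES region caller: 3 DMR(s)
  island:island0     chr1:10000-10500 fold=2.75 q=9.26e-160 hyper in iPS
  island:island2     chr1:60000-60500 fold=2.72 q=5.24e-209 hyper in iPS
iPS vs ES sliding window: 2 DMR(s)
  chr1:10003-10480 sites=27 fold=2.75 classes=cpg_island
  chr1:60012-60489 sites=35 fold=2.72 classes=TSS,cpg_island
unique DMRs per group (one-vs-rest, non-overlapping):
  TEC: 1
  iPS: 0
  ES: 3
```

Both planted memory islands are recovered by the annotated-region caller
and, independently, by the annotation-free sliding window; the three-group
analysis finds DMRs unique to ES and to TEC but none unique to iPS — the
iPSC methylome sits with its tissue of origin, which is exactly the
planted epigenetic memory. `04_cluster_samples.py` confirms it: a two-way
cut of the dendrogram separates the three ES replicates from all TEC and
iPS replicates. `05_variant_inheritance.py` reports

```
heuristic filter: 8/12 retained (rejected: {'caller_filter': 1, 'depth': 2, 'pop_af': 1})
TEC6.1: 8 filtered somatic variants; in all clones: 2, some: 1, none: 5
```

— only the two clone-founding mutations are inherited by every derived
iPSC line.

A `medseq` CLI wraps the same stages (`medseq simulate | catalog |
process | run | cluster`), driven by a YAML config with a seed; rerunning
the same config reproduces every output hash.

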