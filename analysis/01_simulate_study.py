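#!/usr/bin/env python
"""Simulate the three-group methylation study.

Builds a 200-kb toy genome with CpG islands and genes, then a methylome for
three predetermined groups modeled on the study design — renal tubular
epithelial cells (TEC), iPSC clones derived from them (iPS), and embryonic
stem cells (ES) — and writes single-end 50-bp MeD-seq FASTQs per replicate.

Planted structure (the ground truth the later scripts should recover):
  * two "epigenetic memory" islands: methylated in TEC and iPS, not in ES —
    reprogramming did not erase the tissue signature there, so ES differs
    from everything else;
  * one TEC-only island: erased by reprogramming, so TEC differs from both
    stem-cell groups;
  * nothing is planted that would make iPS differ from everybody else.

Outputs: scratch/study/ (genome.fa, genes.bed, islands.bed, *.fastq,
*.truth.tsv, groups.tsv), results/planted_truth.tsv.
"""

from pathlib import Path

import pandas as pd

from medseq import io as mio
from medseq import scan_sites
from medseq import simulate as sim

SEED = 2024
OUT = Path("scratch/study")
RESULTS = Path("results")

GROUPS = {"TEC": 3, "iPS": 3, "ES": 3}
BASELINE_METH = 0.25
MEMORY_DELTA = 0.55      # TEC+iPS hypermethylation at memory loci
# moderate, so the one-vs-rest comparisons of the other groups stay below
# the twofold gate once the signal is diluted into their pooled "rest"
TEC_ONLY_DELTA = 0.40
DEPTH = 40               # expected reads per fully methylated site


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    islands = [("chr1", s, s + 500, 0.08)
               for s in (10_000, 30_000, 60_000, 90_000, 120_000, 150_000)]
    genes = [("chr1", "+", 5_000, 9_000), ("chr1", "-", 55_000, 60_000),
             ("chr1", "+", 115_000, 121_000)]
    gspec = sim.ToyGenomeSpec(
        seed=SEED, contigs=[("chr1", 200_000)], gc_background=0.5,
        cpg_islands=islands, genes=genes, cpg_depletion=0.3,
    )
    genome, genes_df, islands_df = sim.make_toy_genome(gspec)
    mio.write_fasta(genome, OUT / "genome.fa")
    mio.write_bed(genes_df, OUT / "genes.bed")
    mio.write_bed(islands_df, OUT / "islands.bed")

    catalog = scan_sites(genome)
    print(f"genome: 1 contig x 200 kb, {len(catalog)} LpnPI sites, "
          f"{len(islands)} islands, {len(genes)} genes")

    planted = [
        # memory loci: methylated in TEC and in the iPSCs derived from them
        ("chr1", 10_000, 10_500, "TEC", MEMORY_DELTA),
        ("chr1", 10_000, 10_500, "iPS", MEMORY_DELTA),
        ("chr1", 60_000, 60_500, "TEC", MEMORY_DELTA),
        ("chr1", 60_000, 60_500, "iPS", MEMORY_DELTA),
        # a somatic signature fully erased by reprogramming
        ("chr1", 120_000, 120_500, "TEC", TEC_ONLY_DELTA),
    ]
    mspec = sim.MethylomeSpec(
        seed=SEED + 1, groups=GROUPS, baseline_meth=BASELINE_METH,
        planted_dmrs=planted, noise_sd=0.02,
    )
    methylome = sim.plant_methylome(catalog, mspec)
    truth = pd.DataFrame(planted, columns=["contig", "start", "end", "group", "delta"])
    truth.to_csv(RESULTS / "planted_truth.tsv", sep="\t", index=False)

    rows = []
    for k, (sample, group, probs) in enumerate(methylome.iter_samples()):
        cfg = sim.ReadSimConfig(seed=SEED + 100 + k, depth=DEPTH)
        reads, truth_counts = sim.simulate_reads(genome, catalog, probs, cfg, sample=sample)
        sim.write_fastq(reads, OUT / f"{sample}.fastq")
        truth_counts.to_csv(OUT / f"{sample}.truth.tsv", sep="\t")
        rows.append((sample, group, len(reads)))
        print(f"  {sample:10s} ({group}): {len(reads):6d} reads")
    pd.DataFrame(rows, columns=["sample", "group", "n_reads"]).to_csv(
        OUT / "groups.tsv", sep="\t", index=False)
    print(f"wrote study to {OUT}/ and planted truth to {RESULTS}/planted_truth.tsv")


if __name__ == "__main__":
    main()
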