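#!/usr/bin/env python
"""Unsupervised hierarchical clustering of the replicates.

Z-scores the per-region RPM matrix over the DMR regions, clusters sample
columns with complete linkage on city-block distances, and exports the
dendrogram (Newick) and a heatmap. With the planted memory loci, the TEC
and iPS replicates should cluster away from ES.

Inputs: scratch/study/. Outputs: results/dendrogram.nwk,
results/cluster_assignments.tsv, scratch/study/heatmap.png.
"""

from pathlib import Path

import pandas as pd

import medseq
from medseq import io as mio
from medseq.cluster import plot_heatmap

STUDY = Path("scratch/study")
RESULTS = Path("results")


def main() -> None:
    genome = mio.read_fasta(STUDY / "genome.fa")
    catalog = medseq.scan_sites(genome)
    regions = medseq.build_regions(
        mio.read_bed(STUDY / "genes.bed"), mio.read_bed(STUDY / "islands.bed"),
        {c: len(s) for c, s in genome.items()})

    samples = pd.read_csv(STUDY / "groups.tsv", sep="\t")
    tracks, groups = [], {}
    for rec in samples.itertuples(index=False):
        bg = pd.read_csv(STUDY / f"{rec.sample}.sites.bedgraph", sep="\t",
                         names=["chrom", "start", "end", "count"])
        tracks.append(medseq.SiteCountTrack(
            sample=rec.sample, catalog=catalog,
            counts=bg["count"].to_numpy(), n_input_reads=int(rec.n_reads)))
        groups[rec.sample] = rec.group

    table = medseq.normalize_rpm(medseq.aggregate_counts(tracks, regions, catalog))

    # cluster on regions that are differential in any one-vs-rest comparison
    pooled = medseq.pool_groups(table, groups)
    unique, _ = medseq.call_unique_dmrs(pooled, ["TEC", "iPS", "ES"])
    basis = sorted(set().union(*[set(u.index) for u in unique.values()]))
    print(f"clustering {len(samples)} samples on {len(basis)} DMR region(s)")

    z, constant = medseq.zscore_rows(table.rpm.loc[basis])
    result = medseq.hcluster(z)
    nwk = medseq.export_dendrogram(result, str(RESULTS / "dendrogram.nwk"))
    print("dendrogram:", nwk)

    cut = result.cut(2)
    out = pd.DataFrame({
        "sample": list(cut), "cluster": [cut[s] for s in cut],
        "group": [groups[s] for s in cut],
    }).sort_values(["cluster", "sample"])
    out.to_csv(RESULTS / "cluster_assignments.tsv", sep="\t", index=False)
    for cl, sub in out.groupby("cluster"):
        print(f"  cluster {cl}: {', '.join(sub['sample'])}")
    es_cluster = {cut[s] for s in cut if groups[s] == "ES"}
    somatic_cluster = {cut[s] for s in cut if groups[s] != "ES"}
    if es_cluster.isdisjoint(somatic_cluster):
        print("=> a two-way cut separates ES from TEC+iPS: the iPSC lines "
              "cluster with their tissue of origin")

    plot_heatmap(result, str(STUDY / "heatmap.png"))


if __name__ == "__main__":
    main()
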