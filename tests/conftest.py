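import numpy as np
import pandas as pd
import pytest

import medseq
from medseq import simulate as sim


@pytest.fixture(scope="session")
def toy_study():
    """A 200-kb genome with two small islands, two genes and a planted DMR.

    Mild CpG depletion keeps plenty of background LpnPI sites, so a planted
    island is a small fraction of total library weight and its fold change
    is not squeezed by the fixed-library normalization.
    """
    spec = sim.ToyGenomeSpec(
        seed=11,
        contigs=[("chr1", 200_000)],
        cpg_islands=[("chr1", 10_000, 10_500, 0.08), ("chr1", 30_000, 30_500, 0.08)],
        genes=[("chr1", "+", 5_000, 9_000), ("chr1", "-", 20_000, 25_000)],
        cpg_depletion=0.3,
    )
    genome, genes, islands = sim.make_toy_genome(spec)
    catalog = medseq.scan_sites(genome)
    regions = medseq.build_regions(genes, islands, {c: len(s) for c, s in genome.items()})
    return {
        "spec": spec, "genome": genome, "genes": genes, "islands": islands,
        "catalog": catalog, "regions": regions,
    }


@pytest.fixture(scope="session")
def planted_tracks(toy_study):
    """Six count-level replicates (3 per group) with one island hypermethylated in A."""
    catalog = toy_study["catalog"]
    mspec = sim.MethylomeSpec(
        seed=12, groups={"A": 3, "B": 3}, baseline_meth=0.3,
        planted_dmrs=[("chr1", 10_000, 11_000, "A", 0.6)], noise_sd=0.02,
    )
    methylome = sim.plant_methylome(catalog, mspec)
    tracks = []
    groups = {}
    for k, (name, group, probs) in enumerate(methylome.iter_samples()):
        counts = sim.simulate_site_counts(catalog, probs, 100_000, seed=100 + k)
        tracks.append(medseq.SiteCountTrack(
            sample=name, catalog=catalog, counts=counts, n_input_reads=100_000))
        groups[name] = group
    return {"tracks": tracks, "groups": groups, "methylome": methylome}


@pytest.fixture(scope="session")
def pooled_table(toy_study, planted_tracks):
    table = medseq.normalize_rpm(medseq.aggregate_counts(
        planted_tracks["tracks"], toy_study["regions"], toy_study["catalog"]))
    pooled = medseq.pool_groups(table, planted_tracks["groups"])
    return {"table": table, "pooled": pooled}


def make_catalog(positions, contig="chr1"):
    """Catalog from explicit site coordinates (unit-test scaffolding)."""
    rows = [(contig, int(p), "+", "CCGG") for p in sorted(positions)]
    return medseq.LpnPISiteCatalog(
        sites=pd.DataFrame(rows, columns=["contig", "cpg_pos", "strand", "motif"]))
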