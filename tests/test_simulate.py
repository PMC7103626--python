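"""Synthetic genome, methylome and read generators."""

import numpy as np
import pandas as pd
import pytest

from medseq import simulate as sim
from medseq.catalog import scan_sites


def _cpg_per_kb(seq: str) -> float:
    return 1000.0 * seq.count("CG") / max(len(seq), 1)


class TestMakeToyGenome:
    def test_deterministic(self):
        spec = sim.ToyGenomeSpec(seed=3, contigs=[("c", 10_000)],
                                 cpg_islands=[("c", 2000, 3000, 0.1)])
        g1, _, _ = sim.make_toy_genome(spec)
        g2, _, _ = sim.make_toy_genome(spec)
        assert g1 == g2

    def test_island_cpg_enrichment(self):
        spec = sim.ToyGenomeSpec(seed=4, contigs=[("c", 100_000)],
                                 cpg_islands=[("c", 10_000, 11_000, 0.1)])
        genome, _, _ = sim.make_toy_genome(spec)
        seq = genome["c"]
        island = seq[10_000:11_000]
        background = seq[:10_000] + seq[11_000:]
        assert _cpg_per_kb(island) >= 3 * _cpg_per_kb(background)

    def test_degenerate_spec_no_annotations(self):
        genome, genes, islands = sim.make_toy_genome(
            sim.ToyGenomeSpec(seed=5, contigs=[("c", 1000)]))
        assert len(genome["c"]) == 1000
        assert genes.empty and islands.empty

    @pytest.mark.parametrize("bad", [
        dict(cpg_islands=[("c", 100, 300, 0.1), ("c", 200, 400, 0.1)]),  # overlap
        dict(genes=[("c", "+", 100, 2000)]),                             # < 3 kb
        dict(genes=[("c", "+", 100, 20_000)]),                           # out of bounds
    ])
    def test_validation_errors(self, bad):
        with pytest.raises(ValueError):
            sim.ToyGenomeSpec(seed=1, contigs=[("c", 10_000)], **bad).validate()


class TestPlantMethylome:
    def test_group_means_by_construction(self, toy_study):
        cat = toy_study["catalog"]
        spec = sim.MethylomeSpec(seed=1, groups={"A": 2, "B": 2}, baseline_meth=0.5,
                                 planted_dmrs=[("chr1", 10_000, 11_000, "A", 0.4)],
                                 noise_sd=0.0)
        m = sim.plant_methylome(cat, spec)
        inside = cat.sites.index.get_indexer(cat.sites_in_interval("chr1", 10_000, 11_000))
        outside = np.setdiff1d(np.arange(len(cat)), inside)
        assert np.allclose(m.group_means["A"][inside], 0.9)
        assert np.allclose(m.group_means["B"][inside], 0.5)
        assert np.allclose(m.group_means["A"][outside], m.group_means["B"][outside])
        # zero noise: replicates equal the group mean
        for g in ("A", "B"):
            assert np.allclose(m.replicates[g], m.group_means[g][None, :])

    def test_negative_delta_clips_to_zero(self, toy_study):
        cat = toy_study["catalog"]
        spec = sim.MethylomeSpec(seed=1, groups={"A": 1}, baseline_meth=0.5,
                                 planted_dmrs=[("chr1", 10_000, 11_000, "A", -0.5)],
                                 noise_sd=0.0)
        m = sim.plant_methylome(cat, spec)
        inside = cat.sites.index.get_indexer(cat.sites_in_interval("chr1", 10_000, 11_000))
        assert np.allclose(m.group_means["A"][inside], 0.0)

    def test_uncoverable_interval_warns(self, toy_study):
        spec = sim.MethylomeSpec(seed=1, groups={"A": 1},
                                 planted_dmrs=[("chrMissing", 0, 10, "A", 0.3)])
        with pytest.warns(UserWarning, match="uncoverable"):
            m = sim.plant_methylome(toy_study["catalog"], spec)
        assert len(m.uncoverable) == 1


class TestSimulateReads:
    def test_fragment_geometry_and_conservation(self, toy_study):
        genome, cat = toy_study["genome"], toy_study["catalog"]
        cfg = sim.ReadSimConfig(seed=9, depth=5)
        probs = np.full(len(cat), 1.0)
        reads, truth = sim.simulate_reads(genome, cat, probs, cfg)
        assert all(len(seq) == cfg.read_length for _n, seq in reads)
        # conservation: FASTQ records equal the truth-table total
        assert truth["count"].sum() == len(reads)
        # every fragment is genomic sequence: the adapter fill is the suffix
        fill = cfg.adapter[: cfg.read_length - cfg.fragment_length]
        assert all(seq.endswith(fill) for _n, seq in reads)

    def test_zero_methylation_zero_reads(self, toy_study):
        reads, truth = sim.simulate_reads(
            toy_study["genome"], toy_study["catalog"],
            np.zeros(len(toy_study["catalog"])), sim.ReadSimConfig(seed=1, depth=50))
        assert reads == [] and truth["count"].sum() == 0

    def test_binomial_depth_oracle(self):
        # one isolated site, p=0.5, depth 1000: count within 3 binomial SDs
        seq = "A" * 30 + "CCGG" + "A" * 30
        genome = {"c": seq}
        cat = scan_sites(genome)
        assert len(cat) == 1
        _reads, truth = sim.simulate_reads(
            genome, cat, np.array([0.5]), sim.ReadSimConfig(seed=2, depth=1000))
        sd = np.sqrt(1000 * 0.25)
        assert abs(truth["count"].iloc[0] - 500) <= 3 * sd

    def test_edge_site_skipped(self):
        # site 3 bp from the contig start cannot yield a full 32-bp fragment
        genome = {"c": "CCGG" + "A" * 60}
        cat = scan_sites(genome)
        reads, truth = sim.simulate_reads(
            genome, cat, np.ones(len(cat)), sim.ReadSimConfig(seed=3, depth=10))
        assert truth["count"].iloc[0] == 0
        assert len(reads) == truth["count"].sum()


class TestSimulateSiteCounts:
    def test_point_mass_weights(self, toy_study):
        cat = toy_study["catalog"]
        w = np.zeros(len(cat))
        w[0] = 1.0
        counts = sim.simulate_site_counts(cat, w, 500, seed=1)
        assert counts[0] == 500 and counts.sum() == 500

    def test_multinomial_oracle_and_total(self, toy_study):
        cat = toy_study["catalog"]
        n = len(cat)
        counts = sim.simulate_site_counts(cat, np.ones(n), 100 * n, seed=2)
        assert counts.sum() == 100 * n
        sd = np.sqrt(100 * n * (1 / n) * (1 - 1 / n))
        assert np.abs(counts - 100).max() <= 5 * sd

    def test_reproducible_and_zero_weight_error(self, toy_study):
        cat = toy_study["catalog"]
        a = sim.simulate_site_counts(cat, np.ones(len(cat)), 1000, seed=3)
        b = sim.simulate_site_counts(cat, np.ones(len(cat)), 1000, seed=3)
        assert (a == b).all()
        with pytest.raises(ValueError, match="zero"):
            sim.simulate_site_counts(cat, np.zeros(len(cat)), 1000, seed=3)

    def test_calibration_with_depth(self, toy_study):
        # empirical read fractions approach the weight distribution as depth grows
        cat = toy_study["catalog"]
        rng = np.random.default_rng(5)
        w = rng.uniform(0.1, 1.0, len(cat))
        target = w / w.sum()
        errs = []
        for depth in (10_000, 100_000, 1_000_000):
            counts = sim.simulate_site_counts(cat, w, depth, seed=6)
            errs.append(np.abs(counts / depth - target).max())
        assert errs[2] < errs[0]
        assert errs[2] < 1e-3
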