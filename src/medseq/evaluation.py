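"""Probes and benchmarks that measure the pipeline's operating constants.

Rather than reading constants back from configuration, each probe recovers
a pipeline behavior empirically from constructed inputs: the digestion
fragment length from simulated reads, the positional-filter window by
scanning site offsets, the sliding-window and fold gates by bisection, the
variant-filter thresholds by scanning depth and population-AF grids, and
the DMR caller's sensitivity/FDR from planted simulations. Used by the
acceptance machinery and handy for regression checks after refactors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import medseq.aggregate as agg
from . import dmr as dmrmod
from . import pipeline as pipe
from . import simulate as sim
from .catalog import LpnPISiteCatalog, RegionSet, build_regions, scan_sites
from .pipeline import SiteCountTrack
from .variants import heuristic_filter


# ---------------------------------------------------------------------------
# constructed-input probes


def probe_fragment_length(seed: int = 0) -> int:
    """Measured insert length of simulated reads after adapter trimming.

    Simulates a fully methylated single-site genome, trims the adapter off
    every read and returns the (unique) trimmed read length — the digestion
    fragment size.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq = "".join(rng.choice(list(bases), 60))
    # ensure exactly one CCGG site mid-sequence
    seq = seq.replace("CCGG", "CCAA").replace("CG", "CA")
    seq = seq[:28] + "CCGG" + seq[32:]
    genome = {"chr1": seq}
    catalog = scan_sites(genome)
    assert len(catalog) == 1
    cfg = sim.ReadSimConfig(seed=seed, depth=100)
    reads, _truth = sim.simulate_reads(genome, catalog, np.array([1.0]), cfg)
    trimmed, _ = pipe.trim_adapter(reads, cfg.adapter)
    lengths = {len(s) for _n, s in trimmed}
    if len(lengths) != 1:
        raise AssertionError(f"non-unique fragment lengths {lengths}")
    return lengths.pop()


def probe_positional_window(read_length: int = 40) -> tuple[int, int]:
    """Pass window of the positional site filter, scanned from the 5' end.

    Builds reads of ``read_length`` bp carrying a single CCGG whose CpG 'C'
    sits at offset d, for every d where the 3' distance cannot also pass,
    and returns (min, max) passing d.
    """
    passing = []
    scan_max = read_length - 1 - 18 - 2  # keep 3' distance > 17
    for d in range(1, scan_max + 1):
        # CCGG with the CpG 'C' at index d means the motif starts at d-1
        seq = ["A"] * read_length
        seq[d - 1:d + 3] = "CCGG"
        read = [("probe", "".join(seq))]
        kept, _ = pipe.positional_site_filter(read)
        if kept:
            passing.append(d)
    if not passing:
        raise AssertionError("no offset passes the positional filter")
    if passing != list(range(min(passing), max(passing) + 1)):
        raise AssertionError(f"pass window not contiguous: {passing}")
    return min(passing), max(passing)


def _synthetic_catalog(positions_by_contig: dict[str, np.ndarray]) -> LpnPISiteCatalog:
    rows = []
    for contig, pos in positions_by_contig.items():
        for p in pos:
            rows.append((contig, int(p), "+", "CCGG"))
    return LpnPISiteCatalog(
        sites=pd.DataFrame(rows, columns=["contig", "cpg_pos", "strand", "motif"])
    )


def _window_run_reported(n_sites: int, span: int, seed: int = 0) -> bool:
    """Does a strongly differential run of n_sites over span bp yield a DMR?

    The catalog holds 60 background sites plus the probed run; group A
    places heavy weight on the run, group B none.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites in the run")
    gaps = np.full(n_sites - 1, (span - 1) // (n_sites - 1))
    rem = (span - 1) - gaps.sum()
    gaps[:rem] += 1
    run = 10_000 + np.concatenate([[0], np.cumsum(gaps)])
    assert run[-1] - run[0] + 1 == span
    background = 100_000 + np.arange(60) * 500  # well clear of the run
    pos = np.sort(np.concatenate([background, run]))
    catalog = _synthetic_catalog({"chr1": pos})
    in_run = np.isin(pos, run)
    w_a = np.where(in_run, 50.0, 1.0)
    w_b = np.where(in_run, 1.0, 1.0)
    tracks = [
        SiteCountTrack("a", catalog, sim.simulate_site_counts(catalog, w_a, 200_000, seed)),
        SiteCountTrack("b", catalog, sim.simulate_site_counts(catalog, w_b, 200_000, seed + 1)),
    ]
    dmrs = dmrmod.sliding_window_dmrs(
        tracks, {"A": ["a"], "B": ["b"]}, "A", "B", catalog,
        dmrmod.DMRThresholds(window_min_fold=2.0),
    )
    # only count bins covering the probed run
    hit = dmrs[(dmrs["start"] >= run[0] - 1) & (dmrs["end"] <= run[-1] + 2)]
    return len(hit) > 0


def probe_window_min_sites(seed: int = 0, span: int = 400) -> int:
    """Smallest run length reported by the sliding-window caller."""
    for n in range(2, 16):
        if _window_run_reported(n, span, seed):
            return n
    raise AssertionError("no run length up to 15 is reported")


def probe_window_min_span(seed: int = 0, n_sites: int = 12) -> int:
    """Smallest run span (bp) reported, located by scanning candidate spans."""
    reported = None
    for span in range(60, 181, 5):
        if _window_run_reported(n_sites, span, seed):
            reported = span
            break
    if reported is None:
        raise AssertionError("no span up to 180 bp is reported")
    # refine to single-bp resolution
    for span in range(reported - 4, reported + 1):
        if _window_run_reported(n_sites, span, seed):
            return span
    return reported


def probe_region_fold_gate(tol: float = 1e-3) -> float:
    """Fold-change gate of the region caller, located by bisection.

    Constructs large-count, maximally significant single-region tables with
    a prescribed count ratio f and bisects for the smallest f that is
    reported. Counts are large enough that the fold pseudocount is
    negligible, so the returned value estimates the selection threshold.
    """
    meta = pd.DataFrame(
        {"cls": ["TSS"], "contig": ["chr1"], "start": [0], "end": [2000],
         "strand": ["+"], "gene_id": ["g"], "n_sites": [10]},
        index=pd.Index(["TSS:g"], name="region_id"),
    )

    def reported(f: float) -> bool:
        base = 100_000
        counts = pd.DataFrame({"A": [int(round(f * base))], "B": [base]}, index=meta.index)
        libs = pd.Series({"A": 10_000_000, "B": 10_000_000})
        pooled = agg.normalize_rpm(agg.RegionScoreTable(meta=meta, counts=counts, library_sizes=libs))
        return len(dmrmod.call_region_dmrs(pooled, "A", "B")) > 0

    lo, hi = 1.01, 10.0
    if not reported(hi):
        raise AssertionError("even tenfold change is not reported")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if reported(mid):
            hi = mid
        else:
            lo = mid
    return hi


def probe_variant_depth_threshold() -> int:
    """Smallest total read depth retained by the heuristic filter."""
    df = pd.DataFrame({
        "contig": "chr1", "pos": np.arange(1, 31), "ref": "A", "alt": "T",
        "filter_pass": True, "depth": np.arange(1, 31), "vaf": 0.3, "pop_af": 0.0,
    })
    kept, _ = heuristic_filter(df)
    return int(kept["depth"].min())


def probe_variant_popaf_threshold_percent() -> float:
    """Largest population AF retained, in percent, on a fine grid."""
    grid = np.arange(0.0, 1.0001e-3, 1e-5)  # fractions 0 .. 0.1% step 0.001%
    df = pd.DataFrame({
        "contig": "chr1", "pos": np.arange(1, len(grid) + 1), "ref": "A", "alt": "T",
        "filter_pass": True, "depth": 100, "vaf": 0.3, "pop_af": grid,
    })
    kept, _ = heuristic_filter(df)
    return float(kept["pop_af"].max() * 100.0)


def probe_tss_halfwidth() -> tuple[int, int]:
    """(upstream, downstream) extent in bp of a constructed TSS window."""
    genes = pd.DataFrame([{"contig": "chr1", "start": 50_000, "end": 60_000,
                           "strand": "+", "name": "g"}])
    islands = pd.DataFrame(columns=["contig", "start", "end", "name"])
    regions = build_regions(genes, islands)
    tss_row = regions.by_class("TSS").iloc[0]
    return 50_000 - int(tss_row["start"]), int(tss_row["end"]) - 50_000


# ---------------------------------------------------------------------------
# stochastic benchmarks


def _tiled_regions(n_regions: int, sites_per_region: int, spacing: int = 20,
                   gap: int = 400) -> tuple[LpnPISiteCatalog, RegionSet]:
    """A flat landscape of equal-size regions, each covering its own sites."""
    width = (sites_per_region - 1) * spacing + 1
    pitch = width + gap
    pos = []
    recs = []
    for r in range(n_regions):
        start = r * pitch
        pos.extend(start + np.arange(sites_per_region) * spacing)
        recs.append((f"island:r{r}", "cpg_island", "chr1", start, start + width, ".", ""))
    catalog = _synthetic_catalog({"chr1": np.asarray(pos)})
    regions = RegionSet(regions=pd.DataFrame(
        recs, columns=["region_id", "cls", "contig", "start", "end", "strand", "gene_id"]))
    return catalog, regions


def dmr_recovery_benchmark(
    seed: int,
    n_regions: int = 1000,
    sites_per_region: int = 10,
    n_planted: int = 50,
    fold: float = 5.0,
    reads_per_group: int = 1_000_000,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity and observed FDR of the region caller on planted DMRs.

    Half the planted regions are hypermethylated in each group (weight
    ratio = fold), so total weight is balanced and the realized RPM fold of
    a planted region equals ``fold``. One pooled track per group at
    ``reads_per_group`` total reads; BH correction at ``alpha``.
    """
    catalog, regions = _tiled_regions(n_regions, sites_per_region)
    rng = np.random.default_rng(seed)
    planted = rng.choice(n_regions, size=n_planted, replace=False)
    up_in_a = planted[: n_planted // 2]
    up_in_b = planted[n_planted // 2:]

    region_of_site = np.repeat(np.arange(n_regions), sites_per_region)
    w_a = np.ones(len(catalog))
    w_b = np.ones(len(catalog))
    w_a[np.isin(region_of_site, up_in_a)] = fold
    w_b[np.isin(region_of_site, up_in_b)] = fold

    tracks = [
        SiteCountTrack("a", catalog, sim.simulate_site_counts(catalog, w_a, reads_per_group, seed + 1)),
        SiteCountTrack("b", catalog, sim.simulate_site_counts(catalog, w_b, reads_per_group, seed + 2)),
    ]
    table = agg.aggregate(tracks, regions, catalog)
    pooled = agg.pool_groups(table, {"a": "A", "b": "B"})
    th = dmrmod.DMRThresholds(alpha=alpha, correction="bh")
    called = dmrmod.call_region_dmrs(pooled, "A", "B", th)

    planted_ids = {f"island:r{r}" for r in planted}
    called_ids = set(called.index)
    tp = len(called_ids & planted_ids)
    fp = len(called_ids - planted_ids)
    return {
        "n_called": len(called_ids),
        "sensitivity": tp / n_planted,
        "fdr": fp / max(len(called_ids), 1),
    }


def null_fwer_benchmark(
    seed: int,
    n_reps: int = 200,
    n_regions: int = 100,
    sites_per_region: int = 10,
    reads_per_group: int = 100_000,
    alpha: float = 0.05,
) -> dict:
    """Family-wise false-positive rate of the caller under the global null.

    Both groups share uniform site weights; each replicate simulation is
    tested with Bonferroni correction. Reports the fraction of replicates
    with any called DMR (significance + fold gate, as the caller operates)
    and with any Bonferroni-significant region (calibration check).
    """
    catalog, regions = _tiled_regions(n_regions, sites_per_region)
    w = np.ones(len(catalog))
    th = dmrmod.DMRThresholds(alpha=alpha, correction="bonferroni")
    any_dmr = 0
    any_sig = 0
    for rep in range(n_reps):
        tracks = [
            SiteCountTrack("a", catalog, sim.simulate_site_counts(
                catalog, w, reads_per_group, seed + 2 * rep)),
            SiteCountTrack("b", catalog, sim.simulate_site_counts(
                catalog, w, reads_per_group, seed + 2 * rep + 1)),
        ]
        table = agg.aggregate(tracks, regions, catalog)
        pooled = agg.pool_groups(table, {"a": "A", "b": "B"})
        res = dmrmod.region_tests(pooled, "A", "B", th)
        if res["is_dmr"].any():
            any_dmr += 1
        if (res["q"] < alpha).any():
            any_sig += 1
    return {
        "fwer_called": any_dmr / n_reps,
        "fwer_significant": any_sig / n_reps,
        "n_reps": n_reps,
    }


def end_to_end_benchmark(seed: int, target_reads: int = 100_000) -> dict:
    """Full FASTQ-level round trip on a toy genome.

    Simulates ~``target_reads`` MeD-seq reads from one 250-kb contig,
    processes them through trimming, the positional filter, exact mapping
    and site scoring, and reports read accounting plus whether the
    recovered per-site counts equal the simulation truth table.
    """
    spec = sim.ToyGenomeSpec(
        seed=seed,
        contigs=[("chr1", 250_000)],
        cpg_islands=[("chr1", 50_000, 51_000, 0.1), ("chr1", 150_000, 151_000, 0.1)],
        genes=[("chr1", "+", 20_000, 26_000), ("chr1", "-", 100_000, 108_000)],
    )
    genome, _genes, _islands = sim.make_toy_genome(spec)
    catalog = scan_sites(genome)
    meth = 0.5
    depth = max(1, round(target_reads / (len(catalog) * meth)))
    cfg = sim.ReadSimConfig(seed=seed + 1, depth=depth)
    probs = np.full(len(catalog), meth)
    reads, truth = sim.simulate_reads(genome, catalog, probs, cfg, sample="e2e")
    track = pipe.process_sample(reads, genome, catalog, cfg.adapter, sample="e2e")
    track.check_conservation()
    return {
        "n_sites": len(catalog),
        "n_reads": len(reads),
        "truth_total": int(truth["count"].sum()),
        "assigned": track.total_assigned,
        "rejected": {k: int(v) for k, v in track.rejected.items()},
        "conserved": track.total_assigned + sum(track.rejected.values()) == len(reads),
        "truth_exact": bool((track.counts == truth["count"].to_numpy()).all()),
    }
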