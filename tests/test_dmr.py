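"""Chi-squared testing, region and sliding-window DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import medseq
from medseq import simulate as sim
from medseq.dmr import (
    DMRThresholds,
    call_region_dmrs,
    call_unique_dmrs,
    chisq_2x2,
    overlap_annotate,
    sliding_window_dmrs,
    region_tests,
)
from medseq.aggregate import RegionScoreTable, aggregate, normalize_rpm, pool_groups
from medseq.catalog import RegionSet
from medseq.pipeline import SiteCountTrack
from conftest import make_catalog


def brute_force_pearson(a, na, b, nb):
    """Independent oracle: sum (O-E)^2/E over the explicit 2x2 table."""
    table = np.array([[a, na - a], [b, nb - b]], dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestChisq2x2:
    def test_identical_proportions(self):
        stat, p = chisq_2x2(10, 1000, 10, 1000)
        assert stat == 0.0 and p == 1.0

    def test_against_hand_computed_oracle(self):
        stat, _ = chisq_2x2(30, 1000, 10, 1000)
        assert stat == pytest.approx(brute_force_pearson(30, 1000, 10, 1000), abs=1e-12)

    def test_against_scipy_uncorrected(self):
        table = [[30, 970], [10, 990]]
        expected = chi2_contingency(table, correction=False)
        stat, p = chisq_2x2(30, 1000, 10, 1000)
        assert stat == pytest.approx(expected.statistic, abs=1e-10)
        assert p == pytest.approx(expected.pvalue, abs=1e-12)

    def test_degenerate_zero_margin(self):
        assert chisq_2x2(0, 1000, 0, 1000) == (0.0, 1.0)
        assert chisq_2x2(1000, 1000, 1000, 1000) == (0.0, 1.0)

    def test_count_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            chisq_2x2(11, 10, 0, 10)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            na, nb = rng.integers(10, 10_000, size=2)
            a = int(rng.integers(0, na + 1))
            b = int(rng.integers(0, nb + 1))
            if a + b == 0 or (na - a) + (nb - b) == 0:
                continue
            stat, _ = chisq_2x2(a, int(na), b, int(nb))
            assert stat == pytest.approx(
                brute_force_pearson(a, na, b, nb), abs=1e-9, rel=1e-9)


def single_region_pooled(count_a, count_b, lib_a=10**6, lib_b=10**6, cls="TSS"):
    meta = pd.DataFrame(
        {"cls": [cls], "contig": ["chr1"], "start": [0], "end": [2000],
         "strand": ["+"], "gene_id": ["g"], "n_sites": [10]},
        index=pd.Index(["r0"], name="region_id"))
    counts = pd.DataFrame({"A": [count_a], "B": [count_b]}, index=meta.index)
    libs = pd.Series({"A": lib_a, "B": lib_b})
    return normalize_rpm(RegionScoreTable(meta=meta, counts=counts, library_sizes=libs))


class TestRegionCaller:
    def test_significant_large_fold_reported(self):
        pooled = single_region_pooled(30_000, 10_000)
        dmrs = call_region_dmrs(pooled, "A", "B")
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["direction"] == "hyper_a"

    def test_small_fold_gated_despite_significance(self):
        # fold 1.5 with huge counts: q tiny yet below the "more than twofold" gate
        pooled = single_region_pooled(150_000, 100_000)
        res = region_tests(pooled, "A", "B")
        assert res["q"].iloc[0] < 1e-10
        assert not res["is_dmr"].iloc[0]

    def test_label_swap_inverts_direction(self, pooled_table):
        fwd = call_region_dmrs(pooled_table["pooled"], "A", "B")
        rev = call_region_dmrs(pooled_table["pooled"], "B", "A")
        assert set(fwd.index) == set(rev.index)
        for rid in fwd.index:
            assert fwd.loc[rid, "direction"] != rev.loc[rid, "direction"]
            assert fwd.loc[rid, "fold_change"] == pytest.approx(
                1.0 / rev.loc[rid, "fold_change"])

    def test_planted_island_is_the_only_dmr(self, pooled_table):
        dmrs = call_region_dmrs(pooled_table["pooled"], "A", "B")
        assert list(dmrs.index) == ["island:island0"]
        assert dmrs.iloc[0]["direction"] == "hyper_a"

    def test_threshold_monotonicity(self, pooled_table):
        pooled = pooled_table["pooled"]
        n_loose = len(call_region_dmrs(pooled, "A", "B",
                                       DMRThresholds(alpha=0.05, region_min_fold=1.5)))
        n_default = len(call_region_dmrs(pooled, "A", "B"))
        n_tight = len(call_region_dmrs(pooled, "A", "B",
                                       DMRThresholds(alpha=0.001, region_min_fold=5.0)))
        assert n_loose >= n_default >= n_tight


def window_tracks(run_positions, weight=50.0, total=200_000, seed=0):
    background = 100_000 + np.arange(60) * 500
    pos = np.sort(np.concatenate([background, run_positions]))
    cat = make_catalog(pos)
    w_a = np.where(np.isin(pos, run_positions), weight, 1.0)
    tracks = [
        SiteCountTrack("a", cat, sim.simulate_site_counts(cat, w_a, total, seed)),
        SiteCountTrack("b", cat, sim.simulate_site_counts(cat, np.ones(len(pos)), total, seed + 1)),
    ]
    return cat, tracks


class TestSlidingWindow:
    GROUPS = {"A": ["a"], "B": ["b"]}

    def test_planted_run_reported_once(self):
        run = 10_000 + np.arange(12) * 14  # 12 sites spanning 155 bp
        cat, tracks = window_tracks(run)
        dmrs = sliding_window_dmrs(tracks, self.GROUPS, "A", "B", cat)
        covering = dmrs[(dmrs["start"] <= run[0]) & (dmrs["end"] >= run[-1])]
        assert len(covering) == 1
        assert covering.iloc[0]["n_sites"] == 12
        assert covering.iloc[0]["direction"] == "hyper_a"

    def test_nine_sites_insufficient(self):
        run = 10_000 + np.arange(9) * 14  # strong but only 9 sites
        cat, tracks = window_tracks(run)
        dmrs = sliding_window_dmrs(tracks, self.GROUPS, "A", "B", cat)
        assert len(dmrs[(dmrs["start"] >= 9_000) & (dmrs["end"] <= 11_000)]) == 0

    def test_narrow_span_insufficient(self):
        run = 10_000 + np.arange(12) * 7  # 12 sites over only 78 bp
        cat, tracks = window_tracks(run)
        dmrs = sliding_window_dmrs(tracks, self.GROUPS, "A", "B", cat)
        assert len(dmrs[(dmrs["start"] >= 9_000) & (dmrs["end"] <= 11_000)]) == 0

    def test_identical_sample_sets_error(self):
        run = 10_000 + np.arange(12) * 14
        cat, tracks = window_tracks(run)
        with pytest.raises(ValueError, match="identical"):
            sliding_window_dmrs(tracks, {"A": ["a"], "B": ["a"]}, "A", "B", cat)

    def test_direction_flip_breaks_run(self):
        # two adjacent opposing runs: reported separately, not merged
        up = 10_000 + np.arange(12) * 14
        down = up[-1] + 14 + np.arange(12) * 14
        pos = np.sort(np.concatenate([up, down, 100_000 + np.arange(60) * 500]))
        cat = make_catalog(pos)
        w_a = np.where(np.isin(pos, up), 50.0, 1.0)
        w_b = np.where(np.isin(pos, down), 50.0, 1.0)
        tracks = [
            SiteCountTrack("a", cat, sim.simulate_site_counts(cat, w_a, 200_000, 3)),
            SiteCountTrack("b", cat, sim.simulate_site_counts(cat, w_b, 200_000, 4)),
        ]
        dmrs = sliding_window_dmrs(tracks, self.GROUPS, "A", "B", cat)
        local = dmrs[(dmrs["start"] >= 9_000) & (dmrs["end"] <= 12_000)]
        assert len(local) == 2
        assert set(local["direction"]) == {"hyper_a", "hyper_b"}


def three_group_pooled(counts_by_group, lib=10**6):
    n = len(next(iter(counts_by_group.values())))
    meta = pd.DataFrame({
        "cls": ["TSS"] * n, "contig": ["chr1"] * n,
        "start": np.arange(n) * 5000, "end": np.arange(n) * 5000 + 2000,
        "strand": ["+"] * n, "gene_id": [f"g{i}" for i in range(n)],
        "n_sites": [10] * n,
    }, index=pd.Index([f"r{i}" for i in range(n)], name="region_id"))
    counts = pd.DataFrame(counts_by_group, index=meta.index)
    libs = pd.Series({g: lib for g in counts_by_group})
    return normalize_rpm(RegionScoreTable(meta=meta, counts=counts, library_sizes=libs))


class TestUniqueDMRs:
    def test_region_unique_to_one_group(self):
        # region 0 hyper only in ES (2.5-fold: strong enough for ES-vs-rest,
        # diluted below the fold gate in the other one-vs-rest comparisons);
        # region 1 equal everywhere
        pooled = three_group_pooled({
            "ES": [25_000, 5_000], "iPS": [10_000, 5_000], "TEC": [10_000, 5_000]})
        unique, summary = call_unique_dmrs(pooled, ["ES", "iPS", "TEC"])
        assert list(unique["ES"].index) == ["r0"]
        assert len(unique["iPS"]) == 0 and len(unique["TEC"]) == 0
        total = summary[(summary["group"] == "ES") & (summary["cls"] == "total")]
        assert total["n_unique_dmrs"].iloc[0] == 1

    def test_region_differing_everywhere_excluded(self):
        # all three groups pairwise different at region 0: every one-vs-rest
        # comparison calls it, so it is unique to none
        pooled = three_group_pooled({
            "ES": [200_000], "iPS": [25_000], "TEC": [2_000]})
        unique, _ = call_unique_dmrs(pooled, ["ES", "iPS", "TEC"])
        assert all(len(u) == 0 for u in unique.values())

    def test_requires_three_groups(self):
        pooled = three_group_pooled({"ES": [100], "iPS": [100]})
        with pytest.raises(ValueError, match="three groups"):
            call_unique_dmrs(pooled, ["ES", "iPS"])


class TestOverlapAnnotate:
    def test_labels_and_none(self, toy_study):
        dmrs = pd.DataFrame([
            {"contig": "chr1", "start": 10_100, "end": 10_300},   # inside island0
            {"contig": "chr1", "start": 45_000, "end": 45_200},   # intergenic
            {"contig": "chr1", "start": 5_900, "end": 6_100},     # TSS/body boundary
        ])
        out = overlap_annotate(dmrs, toy_study["regions"])
        assert out.loc[0, "classes"] == "cpg_island"
        assert out.loc[1, "classes"] == "none"
        assert out.loc[2, "classes"] == "TSS,gene_body"
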