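"""Differentially methylated region detection.

Two callers, both built on Pearson chi-squared tests of read counts:

* the region caller tests each annotated region (TSS window, gene body,
  CpG island) between two pooled groups, corrects per region class
  (Bonferroni or Benjamini-Hochberg), and keeps regions that are both
  significant and show more than a twofold read-count difference;
* the sliding-window caller tests every LpnPI site genome-wide, bins
  maximal runs of consecutive significant sites with concordant direction,
  and reports bins with at least 10 sites, at least 100 bp span and at
  least a two- or fivefold change.

A three-group mode calls each group against the pooled other two and keeps
DMRs whose intervals overlap no DMR from the other comparisons — the
"unique" DMR sets used to quantify residual tissue-of-origin methylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

from .aggregate import FOLD_PSEUDOCOUNT, RegionScoreTable, fold_change
from .catalog import LpnPISiteCatalog, RegionSet
from .pipeline import SiteCountTrack

DMR_COLUMNS = [
    "contig", "start", "end", "classes", "n_sites",
    "count_a", "count_b", "rpm_a", "rpm_b",
    "fold_change", "direction", "chi2", "p", "q",
    "correction", "caller",
]


@dataclass
class DMRThresholds:
    """Significance and effect-size gates for both callers.

    The region gate is strict (> region_min_fold, "more than twofold");
    the window gates are minima (>=): at least ``window_min_sites`` LpnPI
    sites, at least ``window_min_span_bp`` covered, at least
    ``window_min_fold`` change.
    """

    alpha: float = 0.05
    correction: str = "bh"          # "bonferroni" or "bh"
    region_min_fold: float = 2.0
    window_min_sites: int = 10
    window_min_span_bp: int = 100
    window_min_fold: float = 2.0    # the study used twofold or fivefold
    window_site_correction: str = "bh"  # per-site control; "none" = raw alpha

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.correction not in ("bonferroni", "bh"):
            raise ValueError("correction must be 'bonferroni' or 'bh'")
        if self.window_min_sites < 1:
            raise ValueError("window_min_sites must be >= 1")
        if self.region_min_fold <= 1 or self.window_min_fold <= 1:
            raise ValueError("fold thresholds must exceed 1")


def chisq_2x2(
    count_a: int, total_a: int, count_b: int, total_b: int,
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on the 2x2 table
    [[count_a, total_a - count_a], [count_b, total_b - count_b]].

    A table with any zero expected cell (an empty margin) is degenerate:
    returns (0.0, 1.0).
    """
    if count_a > total_a or count_b > total_b:
        raise ValueError("count exceeds total")
    if min(count_a, count_b, total_a, total_b) < 0 or total_a == 0 or total_b == 0:
        raise ValueError("totals must be positive and counts non-negative")
    n = total_a + total_b
    c1 = count_a + count_b
    c2 = n - c1
    if c1 == 0 or c2 == 0:
        return 0.0, 1.0
    # closed form for 2x2 Pearson chi-squared
    det = count_a * (total_b - count_b) - count_b * (total_a - count_a)
    stat = n * det * det / (total_a * total_b * c1 * c2)
    return float(stat), float(chi2_dist.sf(stat, 1))


def _chisq_2x2_vec(a: np.ndarray, na: int, b: np.ndarray, nb: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized chisq_2x2 for per-site testing (a, b are count arrays)."""
    a = a.astype(float)
    b = b.astype(float)
    n = float(na + nb)
    c1 = a + b
    c2 = n - c1
    det = a * (nb - b) - b * (na - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where((c1 > 0) & (c2 > 0), n * det * det / (na * nb * c1 * c2), 0.0)
    p = chi2_dist.sf(stat, 1)
    p[(c1 == 0) | (c2 == 0)] = 1.0
    return stat, p


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if len(p) == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "none":
        return p.copy()
    raise ValueError(f"unknown correction {method!r}")


def region_tests(
    pooled: RegionScoreTable,
    group_a: str,
    group_b: str,
    thresholds: DMRThresholds | None = None,
) -> pd.DataFrame:
    """Chi-squared test of every region between two pooled groups.

    Returns one row per tested region (site-less regions are excluded) with
    statistics, per-class-adjusted q values, pseudocounted RPM fold change
    and the is_dmr flag (q < alpha and fold strictly above region_min_fold).
    """
    th = thresholds or DMRThresholds()
    th.validate()
    if pooled.rpm is None:
        raise ValueError("pooled table lacks RPM values; use pool_groups/normalize_rpm")
    for g in (group_a, group_b):
        if g not in pooled.counts.columns:
            raise ValueError(f"group {g!r} not in pooled table")

    meta = pooled.meta
    testable = meta.index[meta["n_sites"] > 0]
    lib_a = int(pooled.library_sizes[group_a])
    lib_b = int(pooled.library_sizes[group_b])

    rows = []
    for rid in testable:
        ca = int(pooled.counts.at[rid, group_a])
        cb = int(pooled.counts.at[rid, group_b])
        stat, p = chisq_2x2(ca, lib_a, cb, lib_b)
        ra = float(pooled.rpm.at[rid, group_a])
        rb = float(pooled.rpm.at[rid, group_b])
        fc = fold_change(ra, rb)
        rows.append((rid, meta.at[rid, "cls"], meta.at[rid, "contig"],
                     int(meta.at[rid, "start"]), int(meta.at[rid, "end"]),
                     int(meta.at[rid, "n_sites"]), ca, cb, ra, rb, fc, stat, p))
    res = pd.DataFrame(rows, columns=[
        "region_id", "cls", "contig", "start", "end", "n_sites",
        "count_a", "count_b", "rpm_a", "rpm_b", "fold_change", "chi2", "p",
    ]).set_index("region_id")

    res["q"] = np.nan
    for cls, sub in res.groupby("cls"):
        res.loc[sub.index, "q"] = _adjust(sub["p"].to_numpy(), th.correction)
    res["direction"] = np.where(res["rpm_a"] >= res["rpm_b"], "hyper_a", "hyper_b")
    eff = np.maximum(res["fold_change"], 1.0 / res["fold_change"])
    res["effective_fold"] = eff
    res["is_dmr"] = (res["q"] < th.alpha) & (eff > th.region_min_fold)
    res["correction"] = th.correction
    res["caller"] = "region"
    return res


def call_region_dmrs(
    pooled: RegionScoreTable,
    group_a: str,
    group_b: str,
    thresholds: DMRThresholds | None = None,
) -> pd.DataFrame:
    """Regions passing both the significance and the fold gate."""
    res = region_tests(pooled, group_a, group_b, thresholds)
    return res[res["is_dmr"]].copy()


def _pool_tracks(
    tracks: Sequence[SiteCountTrack], samples: Sequence[str],
) -> tuple[np.ndarray, int]:
    by_name = {t.sample: t for t in tracks}
    counts = sum(by_name[s].counts for s in samples)
    lib = int(sum(by_name[s].total_assigned for s in samples))
    return np.asarray(counts), lib


def sliding_window_dmrs(
    tracks: Sequence[SiteCountTrack],
    groups: Mapping[str, Sequence[str]],
    group_a: str,
    group_b: str,
    catalog: LpnPISiteCatalog,
    thresholds: DMRThresholds | None = None,
) -> pd.DataFrame:
    """Genome-wide scan for runs of sequentially differential LpnPI sites.

    Each site is tested (count vs pooled-library remainder) between the two
    groups; per-site significance is controlled by BH across all sites (or
    raw alpha). Maximal runs of consecutive catalog sites that are all
    significant with the same direction are binned; a bin is reported iff it
    has >= window_min_sites sites, spans >= window_min_span_bp (first to
    last CpG position + 1) and its pooled RPM fold change is >=
    window_min_fold.
    """
    th = thresholds or DMRThresholds()
    th.validate()
    if sorted(groups[group_a]) == sorted(groups[group_b]):
        raise ValueError("groups A and B contain identical sample sets")
    a, lib_a = _pool_tracks(tracks, groups[group_a])
    b, lib_b = _pool_tracks(tracks, groups[group_b])
    if lib_a == 0 or lib_b == 0:
        raise ValueError("a group has zero assigned reads")

    stat, p = _chisq_2x2_vec(a, lib_a, b, lib_b)
    q = _adjust(p, th.window_site_correction)
    sig = q < th.alpha
    rpm_a = a * 1e6 / lib_a
    rpm_b = b * 1e6 / lib_b
    hyper_a = rpm_a >= rpm_b

    records = []
    for contig in catalog.contigs:
        pos = catalog.positions(contig)
        ids = catalog.site_ids(contig)
        idx = catalog.sites.index.get_indexer(ids)
        run: list[int] = []

        def flush(run: list[int]) -> None:
            if not run:
                return
            i0, i1 = run[0], run[-1]
            start = int(pos[i0])
            end = int(pos[i1]) + 1
            n_sites = len(run)
            ca = int(a[idx[run]].sum())
            cb = int(b[idx[run]].sum())
            ra = ca * 1e6 / lib_a
            rb = cb * 1e6 / lib_b
            fc = fold_change(ra, rb)
            eff = max(fc, 1.0 / fc)
            if (n_sites >= th.window_min_sites
                    and end - start >= th.window_min_span_bp
                    and eff >= th.window_min_fold):
                records.append((
                    contig, start, end, n_sites, ca, cb, ra, rb, fc,
                    "hyper_a" if ra >= rb else "hyper_b",
                    float(stat[idx[run]].max()), float(q[idx[run]].max()),
                ))

        prev_dir = None
        for j in range(len(pos)):
            k = idx[j]
            if sig[k]:
                d = bool(hyper_a[k])
                if run and d != prev_dir:
                    flush(run)
                    run = []
                run.append(j)
                prev_dir = d
            else:
                flush(run)
                run = []
        flush(run)

    df = pd.DataFrame(records, columns=[
        "contig", "start", "end", "n_sites", "count_a", "count_b",
        "rpm_a", "rpm_b", "fold_change", "direction", "chi2", "q_max",
    ])
    df["caller"] = "window"
    return df


def call_unique_dmrs(
    pooled3: RegionScoreTable,
    groups: Sequence[str],
    thresholds: DMRThresholds | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """One-vs-rest DMRs unique to each of exactly three groups.

    For each group X the pooled other two form the rest; a DMR of X is
    unique iff its interval overlaps (>= 1 bp) no DMR called in either of
    the other two one-vs-rest comparisons. Returns the per-group unique DMR
    tables and a summary of unique counts per group per region class.
    """
    groups = list(groups)
    if len(groups) != 3:
        raise ValueError("exactly three groups are required")
    for g in groups:
        if g not in pooled3.counts.columns:
            raise ValueError(f"group {g!r} not in pooled table")

    from .aggregate import normalize_rpm

    per_group: dict[str, pd.DataFrame] = {}
    for g in groups:
        rest = [h for h in groups if h != g]
        counts = pd.DataFrame({
            g: pooled3.counts[g],
            "rest": pooled3.counts[rest].sum(axis=1),
        })
        libs = pd.Series({
            g: int(pooled3.library_sizes[g]),
            "rest": int(pooled3.library_sizes[rest].sum()),
        })
        ovr = normalize_rpm(RegionScoreTable(
            meta=pooled3.meta, counts=counts, library_sizes=libs,
        ))
        per_group[g] = call_region_dmrs(ovr, g, "rest", thresholds)

    unique: dict[str, pd.DataFrame] = {}
    for g in groups:
        others = pd.concat(
            [per_group[h] for h in groups if h != g],
            axis=0,
        ) if any(len(per_group[h]) for h in groups if h != g) else pd.DataFrame(
            columns=per_group[g].columns)
        keep = []
        for rid, r in per_group[g].iterrows():
            clash = others[
                (others["contig"] == r["contig"])
                & (others["start"] < r["end"])
                & (others["end"] > r["start"])
            ]
            keep.append(len(clash) == 0)
        unique[g] = per_group[g][np.array(keep, dtype=bool)] if len(per_group[g]) else per_group[g]

    rows = []
    for g in groups:
        u = unique[g]
        for cls in ("TSS", "gene_body", "cpg_island"):
            rows.append((g, cls, int((u["cls"] == cls).sum()) if len(u) else 0))
        rows.append((g, "total", len(u)))
    summary = pd.DataFrame(rows, columns=["group", "cls", "n_unique_dmrs"])
    return unique, summary


def overlap_annotate(dmrs: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Attach annotation-class labels to DMR intervals (>= 1 bp overlap).

    Adds a ``classes`` column: comma-joined labels among TSS, gene_body,
    cpg_island, or "none".
    """
    out = dmrs.copy()
    labels = []
    reg = regions.regions
    for _i, d in out.iterrows():
        hit = reg[
            (reg["contig"] == d["contig"])
            & (reg["start"] < d["end"])
            & (reg["end"] > d["start"])
        ]
        cls = sorted(hit["cls"].unique())
        labels.append(",".join(cls) if cls else "none")
    out["classes"] = labels
    return out
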