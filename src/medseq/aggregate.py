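"""Aggregate per-site counts into per-region read-count scores.

Regions are TSS windows, gene bodies and CpG islands; a site inside
overlapping regions contributes to each (no exclusive assignment).
Reads-per-million normalization makes fold changes comparable across
libraries of unequal size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import LpnPISiteCatalog, RegionSet
from .pipeline import SiteCountTrack

#: Pseudocount added to both RPM values before taking a fold change.
FOLD_PSEUDOCOUNT = 1.0


@dataclass
class RegionScoreTable:
    """Regions x samples count matrix with region metadata.

    ``meta`` carries region_id (index), cls, contig, start, end, strand and
    n_sites; ``counts`` shares the index, one column per sample;
    ``library_sizes`` maps sample -> total assigned reads. Regions covering
    no catalog site are flagged via n_sites == 0.
    """

    meta: pd.DataFrame
    counts: pd.DataFrame
    library_sizes: pd.Series
    rpm: pd.DataFrame | None = field(default=None)

    @property
    def siteless(self) -> pd.Index:
        return self.meta.index[self.meta["n_sites"] == 0]

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative region counts")
        for s in self.counts.columns:
            if (self.counts[s] > self.library_sizes[s]).any():
                raise ValueError(f"region count exceeds library size for {s}")


def aggregate(
    tracks: Sequence[SiteCountTrack],
    regions: RegionSet,
    catalog: LpnPISiteCatalog,
) -> RegionScoreTable:
    """Sum site counts over each region interval for every sample."""
    known = set(catalog.contigs)
    unknown = set(regions.regions["contig"]) - known
    if unknown:
        raise ValueError(f"region set references unknown contig(s): {sorted(unknown)}")

    meta = regions.regions.set_index("region_id").copy()
    site_lists = {}
    for rid, r in meta.iterrows():
        ids = catalog.sites_in_interval(r.contig, r.start, r.end)
        site_lists[rid] = catalog.sites.index.get_indexer(ids)
    meta["n_sites"] = pd.Series({rid: len(v) for rid, v in site_lists.items()})

    cols = {}
    libs = {}
    for t in tracks:
        cols[t.sample] = [int(t.counts[idx].sum()) for idx in site_lists.values()]
        libs[t.sample] = t.total_assigned
    counts = pd.DataFrame(cols, index=meta.index)
    return RegionScoreTable(meta=meta, counts=counts, library_sizes=pd.Series(libs))


def normalize_rpm(table: RegionScoreTable) -> RegionScoreTable:
    """Attach reads-per-million values; the raw counts are retained."""
    zero = table.library_sizes[table.library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    rpm = table.counts * 1e6 / table.library_sizes
    return RegionScoreTable(
        meta=table.meta, counts=table.counts,
        library_sizes=table.library_sizes, rpm=rpm,
    )


def pool_groups(
    table: RegionScoreTable,
    groups: Mapping[str, str],
) -> RegionScoreTable:
    """Sum raw counts and library sizes over the samples of each group.

    ``groups`` maps sample -> group name, or group name -> list of samples.
    """
    if groups and isinstance(next(iter(groups.values())), str):
        missing = [s for s in table.counts.columns if s not in groups]
        if missing:
            raise ValueError(f"sample(s) without group assignment: {missing}")
        by_group: dict[str, list[str]] = {}
        for sample in table.counts.columns:
            by_group.setdefault(groups[sample], []).append(sample)
    else:
        by_group = {g: list(members) for g, members in groups.items()}
        assigned = [s for members in by_group.values() for s in members]
        if len(set(assigned)) != len(assigned):
            raise ValueError("a sample is assigned to more than one group")
        missing = [s for s in table.counts.columns if s not in assigned]
        if missing:
            raise ValueError(f"sample(s) without group assignment: {missing}")
    empty = [g for g, members in by_group.items() if not members]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    counts = pd.DataFrame(
        {g: table.counts[members].sum(axis=1) for g, members in by_group.items()}
    )
    libs = pd.Series({g: int(table.library_sizes[m].sum()) for g, m in by_group.items()})
    pooled = RegionScoreTable(meta=table.meta, counts=counts, library_sizes=libs)
    return normalize_rpm(pooled)


def fold_change(rpm_a: float, rpm_b: float, pseudocount: float = FOLD_PSEUDOCOUNT) -> float:
    """Pseudocounted RPM ratio A/B; bounded away from 0/inf at zero counts."""
    return (rpm_a + pseudocount) / (rpm_b + pseudocount)
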