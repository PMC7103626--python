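"""From raw MeD-seq reads to per-LpnPI-site counts.

Stages: Illumina adapter trimming, optional host-read removal (for lines
grown on feeder cells of another species), the positional restriction-site
filter (a read must carry the motif's CpG 13-17 bp from either end, the
geometric signature of LpnPI digestion), exact-match mapping for toy
genomes or SAM import for externally aligned data, and assignment of each
placement to a catalog site.

Read accounting is conserved at every stage: assigned + rejected-by-reason
equals the input read count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    DEFAULT_MOTIF,
    LpnPISiteCatalog,
    iupac_to_regex,
    reverse_complement,
)

#: Inclusive window (in bp, 0-based index of the CpG 'C') from either read
#: end within which an LpnPI site must occur for a read to pass.
SITE_WINDOW = (13, 17)

#: Minimum exact suffix/prefix overlap for adapter trimming.
MIN_ADAPTER_OVERLAP = 5
#: Reads shorter than this after trimming are dropped.
MIN_READ_LENGTH = 20


@dataclass
class Placement:
    """One exact or aligned genomic location of a read."""

    read: str
    contig: str
    start: int
    end: int
    strand: str
    multi: bool = False


@dataclass
class SiteCountTrack:
    """Per-sample read counts assigned to each catalog site."""

    sample: str
    catalog: LpnPISiteCatalog
    counts: np.ndarray
    rejected: dict[str, int] = field(default_factory=dict)
    n_input_reads: int = 0

    @property
    def total_assigned(self) -> int:
        return int(self.counts.sum())

    def check_conservation(self) -> None:
        total = self.total_assigned + sum(self.rejected.values())
        if total != self.n_input_reads:
            raise AssertionError(
                f"{self.sample}: assigned {self.total_assigned} + rejected "
                f"{sum(self.rejected.values())} != input {self.n_input_reads}"
            )

    def to_bedgraph(self) -> pd.DataFrame:
        s = self.catalog.sites
        return pd.DataFrame({
            "chrom": s["contig"],
            "start": s["cpg_pos"],
            "end": s["cpg_pos"] + 1,
            "value": self.counts,
        })


def trim_adapter(
    reads: Sequence[tuple[str, str]],
    adapter: str,
    min_overlap: int = MIN_ADAPTER_OVERLAP,
    min_length: int = MIN_READ_LENGTH,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Remove the longest read suffix that exactly matches an adapter prefix.

    Matches shorter than ``min_overlap`` are ignored; reads shorter than
    ``min_length`` after trimming are dropped and counted.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    out = []
    stats = {"trimmed": 0, "untrimmed": 0, "dropped_short": 0}
    for name, seq in reads:
        kmax = min(len(seq), len(adapter))
        cut = None
        for k in range(kmax, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = k
                break
        if cut is None:
            stats["untrimmed"] += 1
            trimmed = seq
        else:
            stats["trimmed"] += 1
            trimmed = seq[:-cut]
        if len(trimmed) < min_length:
            stats["dropped_short"] += 1
        else:
            out.append((name, trimmed))
    return out, stats


class ExactMatcher:
    """Seed-and-verify exact full-length matcher over a small genome.

    A k-mer index over both the forward genome and (implicitly, via
    reverse-complementing the query) the reverse strand; any full-length
    exact match must agree with the read's first k bases, so seed hits are
    exhaustive. Reads shorter than k fall back to a direct scan.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 16):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((contig, i))

    def _hits(self, query: str) -> list[tuple[str, int]]:
        if len(query) < self.k:
            out = []
            for contig, seq in self.genome.items():
                start = 0
                while (i := seq.find(query, start)) != -1:
                    out.append((contig, i))
                    start = i + 1
            return out
        n = len(query)
        return [
            (c, i) for c, i in self.index.get(query[: self.k], ())
            if self.genome[c][i:i + n] == query
        ]

    def match(self, seq: str) -> list[tuple[str, int, int, str]]:
        """All exact full-length placements of seq, as (contig,start,end,strand)."""
        seq = seq.upper()
        found = {}
        for contig, i in self._hits(seq):
            found[(contig, i, i + len(seq))] = "+"
        for contig, i in self._hits(reverse_complement(seq)):
            found.setdefault((contig, i, i + len(seq)), "-")
        return [(c, s, e, st) for (c, s, e), st in sorted(found.items())]

    def contains(self, seq: str) -> bool:
        return bool(self._hits(seq.upper()) or self._hits(reverse_complement(seq.upper())))


def filter_host_reads(
    reads: Sequence[tuple[str, str]],
    host: ExactMatcher,
    target: ExactMatcher,
) -> tuple[list[tuple[str, str]], int]:
    """Drop reads specific to the host genome.

    A read is removed iff it matches the host genome exactly and has no
    exact match in the target genome (target matches take precedence).
    Returns (retained reads, number removed).
    """
    kept, removed = [], 0
    for name, seq in reads:
        if host.contains(seq) and not target.contains(seq):
            removed += 1
        else:
            kept.append((name, seq))
    return kept, removed


def _read_site_offsets(seq: str, fwd: re.Pattern, rev: re.Pattern, k: int,
                       anchor: str = "C") -> list[int]:
    """0-based read indices of CpG anchors of motif instances (both strands).

    The anchor is the first base of the CG dinucleotide ("C", the default)
    or its second base ("G", the cytosine of the opposite strand) — the
    mirror image of the "C" convention under reverse complementation.
    """
    if anchor not in ("C", "G"):
        raise ValueError("anchor must be 'C' or 'G'")
    shift = 0 if anchor == "C" else 1
    offsets = set()
    for pattern in (fwd, rev):
        for m in pattern.finditer(seq):
            i = seq.find("CG", m.start(), m.start() + k)
            if i != -1:
                offsets.add(i + shift)
    return sorted(offsets)


def positional_site_filter(
    reads: Sequence[tuple[str, str]],
    motif: str = DEFAULT_MOTIF,
    window: tuple[int, int] = SITE_WINDOW,
    anchor: str = "C",
) -> tuple[list[tuple[str, str]], int]:
    """Keep reads carrying an LpnPI site 13-17 bp from either end.

    A read passes iff some motif instance (either orientation) has its CpG
    anchor base at 0-based index d from the 5' end or e = len-1-d from the
    3' end with window[0] <= d <= window[1] or window[0] <= e <= window[1].
    The anchor is the CG's first base by default; filtering a
    reverse-complemented read with the mirrored anchor ("G") reproduces the
    original decision exactly.

    Returns (passing reads, number rejected).
    """
    fwd = re.compile(f"(?=({iupac_to_regex(motif)}))")
    rev = re.compile(f"(?=({iupac_to_regex(reverse_complement(motif))}))")
    k = len(motif)
    lo, hi = window
    kept, rejected = [], 0
    for name, seq in reads:
        seq_u = seq.upper()
        n = len(seq_u)
        ok = any(
            lo <= d <= hi or lo <= (n - 1 - d) <= hi
            for d in _read_site_offsets(seq_u, fwd, rev, k, anchor)
        )
        if ok:
            kept.append((name, seq))
        else:
            rejected += 1
    return kept, rejected


def map_reads_exact(
    reads: Sequence[tuple[str, str]],
    genome: Mapping[str, str] | ExactMatcher,
) -> tuple[list[Placement], int]:
    """Place each read at all exact full-length matches (both strands).

    Reads with no match are counted unmapped; reads with several matches
    are flagged multi on every placement. Mismatches are not tolerated:
    this matcher targets error-free toy data, real alignments enter via
    :func:`import_sam`.
    """
    matcher = genome if isinstance(genome, ExactMatcher) else ExactMatcher(genome)
    placements: list[Placement] = []
    unmapped = 0
    for name, seq in reads:
        hits = matcher.match(seq)
        if not hits:
            unmapped += 1
            continue
        multi = len(hits) > 1
        for contig, start, end, strand in hits:
            placements.append(Placement(name, contig, start, end, strand, multi))
    return placements, unmapped


def import_sam(
    path: str,
    catalog: LpnPISiteCatalog,
) -> tuple[list[Placement], int]:
    """Convert a SAM/BAM file into placements against the catalog's genome.

    Primary alignments become placements; records that additionally carry
    secondary/supplementary alignments are flagged multi. Returns
    (placements, unmapped count). Contigs absent from the catalog raise.
    """
    import pysam

    known = set(catalog.contigs)
    placements: list[Placement] = []
    unmapped = 0
    secondary_of: dict[str, list[Placement]] = {}
    bad: set[str] = set()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                unmapped += 1
                continue
            if rec.reference_name not in known:
                bad.add(rec.reference_name)
                continue
            p = Placement(
                rec.query_name, rec.reference_name,
                rec.reference_start, rec.reference_end,
                "-" if rec.is_reverse else "+",
            )
            if rec.is_secondary or rec.is_supplementary:
                secondary_of.setdefault(rec.query_name, []).append(p)
            else:
                placements.append(p)
    if bad:
        raise ValueError(f"SAM contigs absent from catalog genome: {sorted(bad)}")
    with_secondary = set(secondary_of)
    for p in placements:
        if p.read in with_secondary:
            p.multi = True
    for name, extra in secondary_of.items():
        for p in extra:
            p.multi = True
            placements.append(p)
    return placements, unmapped


def score_sites(
    placements: Sequence[Placement],
    catalog: LpnPISiteCatalog,
    sample: str = "sample",
    window: tuple[int, int] = SITE_WINDOW,
    n_input_reads: int | None = None,
    prior_rejections: Mapping[str, int] | None = None,
) -> SiteCountTrack:
    """Assign each read one count at one catalog site.

    A placement is assignable to sites whose CpG position lies within it at
    13-17 bp from either placement end; among several, the site nearest the
    placement midpoint wins (lower coordinate on ties). A multi-mapped read
    contributes a single count, at the lowest-coordinate placement that has
    an assignable site. Unassignable reads are tallied by reason.
    """
    lo, hi = window
    by_read: dict[str, list[Placement]] = {}
    for p in placements:
        by_read.setdefault(p.read, []).append(p)

    counts = np.zeros(len(catalog), dtype=np.int64)
    rejected = dict(prior_rejections or {})
    rejected.setdefault("no_catalog_site", 0)
    for name, plist in by_read.items():
        plist.sort(key=lambda p: (p.contig, p.start))
        assigned = False
        for p in plist:
            pos, ids = (catalog.positions(p.contig), catalog.site_ids(p.contig))
            a, b = np.searchsorted(pos, [p.start, p.end])
            best = None
            mid = (p.start + p.end - 1) / 2
            for cpg, sid in zip(pos[a:b], ids[a:b]):
                d = cpg - p.start
                e = (p.end - 1) - cpg
                if lo <= d <= hi or lo <= e <= hi:
                    key = (abs(cpg - mid), cpg)
                    if best is None or key < best[0]:
                        best = (key, sid)
            if best is not None:
                counts[catalog.sites.index.get_loc(best[1])] += 1
                assigned = True
                break
        if not assigned:
            rejected["no_catalog_site"] += 1

    track = SiteCountTrack(
        sample=sample,
        catalog=catalog,
        counts=counts,
        rejected=rejected,
        n_input_reads=len(by_read) if n_input_reads is None else n_input_reads,
    )
    return track


def process_sample(
    reads: Sequence[tuple[str, str]],
    genome: Mapping[str, str] | ExactMatcher,
    catalog: LpnPISiteCatalog,
    adapter: str,
    sample: str = "sample",
    host: ExactMatcher | None = None,
    motif: str = DEFAULT_MOTIF,
    window: tuple[int, int] = SITE_WINDOW,
) -> SiteCountTrack:
    """Full per-sample pipeline: trim, host-filter, site-filter, map, score.

    Conservation holds: track.total_assigned + sum(track.rejected.values())
    == len(reads).
    """
    matcher = genome if isinstance(genome, ExactMatcher) else ExactMatcher(genome)
    n_input = len(reads)
    rejections: dict[str, int] = {}

    trimmed, tstats = trim_adapter(reads, adapter)
    rejections["too_short_after_trim"] = tstats["dropped_short"]

    if host is not None:
        trimmed, n_host = filter_host_reads(trimmed, host, matcher)
        rejections["host"] = n_host

    passing, n_rej = positional_site_filter(trimmed, motif=motif, window=window)
    rejections["no_site_in_window"] = n_rej

    placements, n_unmapped = map_reads_exact(passing, matcher)
    rejections["unmapped"] = n_unmapped

    track = score_sites(
        placements, catalog, sample=sample, window=window,
        n_input_reads=n_input, prior_rejections=rejections,
    )
    track.check_conservation()
    return track
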