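"""LpnPI recognition-site catalog and genomic region definitions.

MeD-seq reads out DNA methylation through the methylation-dependent
restriction enzyme LpnPI, which cuts around methylated CpG-containing
recognition sites. The catalog enumerates every CpG-bearing motif instance
in a reference genome; downstream stages assign read counts to these sites
and aggregate them over annotated regions (TSS windows, gene bodies, CpG
islands).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: IUPAC nucleotide codes -> allowed bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Default LpnPI recognition motif (the enzyme's published specificity);
#: configurable because only the CpG requirement is fixed by the read-out.
DEFAULT_MOTIF = "CCDG"

#: Half-width of the TSS window in bp (1 kb upstream through 1 kb downstream).
TSS_HALFWIDTH = 1000

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_to_regex(motif: str) -> str:
    """Expand an IUPAC motif into a character-class regex."""
    parts = []
    for base in motif.upper():
        if base not in IUPAC:
            raise ValueError(f"invalid IUPAC code {base!r} in motif {motif!r}")
        allowed = IUPAC[base]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return "".join(parts)


@dataclass
class LpnPISiteCatalog:
    """Genome-wide list of LpnPI read-out sites.

    ``sites`` has one row per distinct read-out position with columns
    ``contig``, ``cpg_pos`` (0-based + strand coordinate of the CpG 'C'),
    ``strand`` ('+', '-' or '+-' when motif instances on both strands share
    the position), and ``motif`` (the + strand genomic sequence of one
    matched instance). Rows are sorted by (contig, cpg_pos); the row index
    is the stable site id used by count tracks.
    """

    sites: pd.DataFrame
    motif: str = DEFAULT_MOTIF
    require_cpg: bool = True
    _positions: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for contig, sub in self.sites.groupby("contig", sort=False):
            pos = sub["cpg_pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"site positions not strictly increasing on {contig}")
            self._positions[contig] = (pos, sub.index.to_numpy())

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def contigs(self) -> list[str]:
        return list(self._positions)

    def positions(self, contig: str) -> np.ndarray:
        """Sorted site coordinates on one contig (empty if none)."""
        return self._positions.get(contig, (np.empty(0, dtype=int), None))[0]

    def site_ids(self, contig: str) -> np.ndarray:
        return self._positions.get(contig, (None, np.empty(0, dtype=int)))[1]

    def sites_in_interval(self, contig: str, start: int, end: int) -> np.ndarray:
        """Site ids with cpg_pos in the half-open interval [start, end)."""
        pos, ids = self._positions.get(contig, (np.empty(0, dtype=int), np.empty(0, dtype=int)))
        lo, hi = np.searchsorted(pos, [start, end])
        return ids[lo:hi]

    def to_bed(self) -> pd.DataFrame:
        """BED6 view: one 1-bp record per site, name=motif/strand."""
        s = self.sites
        return pd.DataFrame({
            "chrom": s["contig"],
            "start": s["cpg_pos"],
            "end": s["cpg_pos"] + 1,
            "name": s["motif"] + "/" + s["strand"],
            "score": 0,
            "strand": s["strand"].str[0],
        })


def _find_cg(seq: str, start: int, end: int) -> int | None:
    """Leftmost 0-based index of the C of a CG dinucleotide in seq[start:end]."""
    i = seq.find("CG", start, end)
    return i if i != -1 else None


def scan_sites(
    genome: Mapping[str, str],
    motif: str = DEFAULT_MOTIF,
    require_cpg: bool = True,
) -> LpnPISiteCatalog:
    """Enumerate motif instances on both strands of a genome.

    Each instance is keyed by its read-out position: the + strand coordinate
    of the C of the leftmost CG dinucleotide inside the instance span (CG is
    its own reverse complement, so the same coordinate serves both strands).
    Instances sharing a read-out position are merged into one catalog entry.
    With ``require_cpg`` off, CG-less instances are kept and keyed by their
    motif start.
    """
    fwd = re.compile(f"(?=({iupac_to_regex(motif)}))")
    rev = re.compile(f"(?=({iupac_to_regex(reverse_complement(motif))}))")
    k = len(motif)

    records: list[tuple[str, int, str, str]] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        merged: dict[int, tuple[str, str]] = {}
        for pattern, strand in ((fwd, "+"), (rev, "-")):
            for m in pattern.finditer(seq):
                s = m.start()
                cg = _find_cg(seq, s, s + k)  # CG fully inside the span
                if cg is None:
                    if require_cpg:
                        continue
                    key = s
                else:
                    key = cg
                if key in merged:
                    old_motif, old_strand = merged[key]
                    if strand not in old_strand:
                        merged[key] = (old_motif, "+-")
                else:
                    merged[key] = (seq[s:s + k], strand)
        for pos in sorted(merged):
            motif_seq, strand = merged[pos]
            records.append((contig, pos, strand, motif_seq))

    sites = pd.DataFrame(records, columns=["contig", "cpg_pos", "strand", "motif"])
    return LpnPISiteCatalog(sites=sites, motif=motif, require_cpg=require_cpg)


# ---------------------------------------------------------------------------
# Annotated regions


@dataclass
class RegionSet:
    """TSS windows, gene bodies and CpG islands as one interval table.

    ``regions`` columns: region_id, cls (TSS/gene_body/cpg_island), contig,
    start, end, strand, gene_id (empty for islands).
    """

    regions: pd.DataFrame

    def __len__(self) -> int:
        return len(self.regions)

    def by_class(self, cls: str) -> pd.DataFrame:
        return self.regions[self.regions["cls"] == cls]


def build_regions(
    genes: pd.DataFrame,
    islands: pd.DataFrame,
    contig_lengths: Mapping[str, int] | None = None,
    tss_halfwidth: int = TSS_HALFWIDTH,
) -> RegionSet:
    """Derive TSS windows and gene bodies from gene models; pass islands through.

    The TSS window spans 1 kb before through 1 kb after the transcription
    start site in transcription orientation; the gene body runs from 1 kb
    after the TSS to the transcription end site. A gene body shorter than
    the 1-kb window (gene < 2 kb) is dropped; the TSS window is kept.

    ``genes`` needs columns contig, start, end, strand (and optionally name);
    ``islands`` needs contig, start, end (optionally name). Intervals are
    0-based half-open; regions are clipped to contig bounds when lengths are
    given.
    """
    recs = []

    def clip(contig: str, lo: int, hi: int) -> tuple[int, int]:
        lo = max(lo, 0)
        if contig_lengths is not None:
            hi = min(hi, contig_lengths[contig])
        return lo, hi

    for i, g in enumerate(genes.itertuples(index=False)):
        contig, start, end, strand = g.contig, int(g.start), int(g.end), g.strand
        if start >= end:
            raise ValueError(f"gene record {i}: empty interval [{start},{end})")
        if strand not in "+-":
            raise ValueError(f"gene record {i}: bad strand {strand!r}")
        gid = getattr(g, "name", None) or f"gene{i}"
        tss = start if strand == "+" else end
        lo, hi = clip(contig, tss - tss_halfwidth, tss + tss_halfwidth)
        recs.append((f"TSS:{gid}", "TSS", contig, lo, hi, strand, gid))
        if end - start >= 2 * tss_halfwidth:
            if strand == "+":
                blo, bhi = clip(contig, tss + tss_halfwidth, end)
            else:
                blo, bhi = clip(contig, start, tss - tss_halfwidth)
            if bhi > blo:
                recs.append((f"body:{gid}", "gene_body", contig, blo, bhi, strand, gid))

    for i, isl in enumerate(islands.itertuples(index=False)):
        name = getattr(isl, "name", None) or f"island{i}"
        lo, hi = clip(isl.contig, int(isl.start), int(isl.end))
        recs.append((f"island:{name}", "cpg_island", isl.contig, lo, hi, ".", ""))

    df = pd.DataFrame(
        recs, columns=["region_id", "cls", "contig", "start", "end", "strand", "gene_id"]
    )
    return RegionSet(regions=df)


def classify_sites(catalog: LpnPISiteCatalog, regions: RegionSet) -> pd.Series:
    """Map each catalog site id to its list of region classes.

    A site may fall in several classes (e.g. an island inside a TSS window);
    sites covered by no region are labeled ``distal``. Containment is
    half-open on the CpG position.
    """
    labels: dict[int, list[str]] = {sid: [] for sid in catalog.sites.index}
    for r in regions.regions.itertuples(index=False):
        for sid in catalog.sites_in_interval(r.contig, r.start, r.end):
            if r.cls not in labels[sid]:
                labels[sid].append(r.cls)
    return pd.Series(
        {sid: (v if v else ["distal"]) for sid, v in labels.items()}, name="classes"
    ).sort_index()
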