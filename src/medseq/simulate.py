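"""Synthetic genomes, methylomes and MeD-seq reads.

Everything downstream of sequencing is testable without real data: a toy
genome with CpG islands and genes, per-site methylation probabilities with
group structure and planted differentially methylated intervals, and a
digestion/sequencing simulator that emits 32-bp LpnPI fragments padded with
adapter sequence to 50-bp single-end reads. All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import LpnPISiteCatalog, reverse_complement

log = logging.getLogger(__name__)

#: LpnPI digestion excises ~32 bp around the methylated CpG-containing site.
FRAGMENT_LENGTH = 32
#: Single-end read length of the sequencing run.
READ_LENGTH = 50
#: Fragment offsets at which the CpG 'C' may sit, so the site lies 13-17 bp
#: from a read end after trimming.
CPG_FRAGMENT_OFFSETS = (15, 16)

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASES = np.array(list("ACGT"))


@dataclass
class ToyGenomeSpec:
    """Recipe for a small random genome with islands and genes.

    Intervals are 0-based half-open. Genes must be >= 3 kb so the TSS window
    and gene body are disjoint and non-empty; islands must not overlap.
    ``cpg_islands`` entries are (contig, start, end, cpg_density) where the
    density is the per-step probability of emitting a CCGG block (an LpnPI
    site containing a CpG) while writing the island sequence.
    """

    seed: int
    contigs: Sequence[tuple[str, int]]
    gc_background: float = 0.5
    cpg_islands: Sequence[tuple[str, int, int, float]] = ()
    genes: Sequence[tuple[str, str, int, int]] = ()
    #: Fraction of background CG dinucleotides mutated away (vertebrate
    #: genomes are CpG-depleted outside islands; this keeps islands >= 3x
    #: enriched over background).
    cpg_depletion: float = 0.85

    def validate(self) -> None:
        lengths = dict(self.contigs)
        if not 0.0 <= self.gc_background <= 1.0:
            raise ValueError("gc_background must be in [0,1]")
        if not 0.0 <= self.cpg_depletion <= 1.0:
            raise ValueError("cpg_depletion must be in [0,1]")
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end, dens in self.cpg_islands:
            if contig not in lengths:
                raise ValueError(f"island on unknown contig {contig!r}")
            if not (0 <= start < end <= lengths[contig]):
                raise ValueError(f"island [{start},{end}) outside {contig}")
            if not 0.0 < dens <= 1.0:
                raise ValueError("island cpg_density must be in (0,1]")
            by_contig.setdefault(contig, []).append((start, end))
        for contig, ivals in by_contig.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping islands on {contig}: [{s1},{e1}) and [{s2},{e2})")
        for contig, strand, start, end in self.genes:
            if contig not in lengths:
                raise ValueError(f"gene on unknown contig {contig!r}")
            if not (0 <= start < end <= lengths[contig]):
                raise ValueError(f"gene [{start},{end}) outside {contig}")
            if end - start < 3000:
                raise ValueError(f"gene [{start},{end}) shorter than 3 kb")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")


@dataclass
class MethylomeSpec:
    """Group-structured per-site methylation probabilities with planted DMRs.

    ``groups`` maps group name -> replicate count (the study compared three
    predetermined groups: iPSC lines, control ESCs and renal epithelial
    lines). ``planted_dmrs`` entries are (contig, start, end, group, delta):
    inside the interval the target group's mean methylation is shifted by
    delta (clipped to [0,1]); elsewhere all groups share ``baseline_meth``.
    Replicates add Gaussian noise with sd ``noise_sd``, clipped.
    """

    seed: int
    groups: Mapping[str, int]
    baseline_meth: float = 0.5
    planted_dmrs: Sequence[tuple[str, int, int, str, float]] = ()
    noise_sd: float = 0.02
    min_sites: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.baseline_meth <= 1.0:
            raise ValueError("baseline_meth must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for contig, start, end, group, _delta in self.planted_dmrs:
            if group not in self.groups:
                raise ValueError(f"planted DMR targets unknown group {group!r}")
            if start >= end:
                raise ValueError(f"empty planted interval [{start},{end}) on {contig}")


@dataclass
class ReadSimConfig:
    """Digestion and sequencing geometry.

    ``depth`` is the binomial number-of-trials per site: the expected read
    count at a fully methylated site.
    """

    seed: int = 0
    fragment_length: int = FRAGMENT_LENGTH
    read_length: int = READ_LENGTH
    adapter: str = DEFAULT_ADAPTER
    depth: int = 50

    def validate(self) -> None:
        if self.fragment_length > self.read_length:
            raise ValueError("fragment_length must be <= read_length")
        if len(self.adapter) < self.read_length - self.fragment_length:
            raise ValueError("adapter too short to fill read_length - fragment_length")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class Methylome:
    """Per-group, per-replicate methylation probability per catalog site."""

    group_means: dict[str, np.ndarray]          # group -> (n_sites,)
    replicates: dict[str, np.ndarray]           # group -> (n_reps, n_sites)
    uncoverable: list[tuple[str, int, int, str, float]] = field(default_factory=list)

    def sample_names(self) -> list[str]:
        return [f"{g}_rep{i}" for g, arr in self.replicates.items() for i in range(arr.shape[0])]

    def iter_samples(self):
        for g, arr in self.replicates.items():
            for i in range(arr.shape[0]):
                yield f"{g}_rep{i}", g, arr[i]


def make_toy_genome(
    spec: ToyGenomeSpec,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate (genome, genes BED table, islands BED table).

    Background sequence is i.i.d. with the configured GC fraction, then
    CpG-depleted (most background CG dinucleotides are mutated away, as in
    vertebrate genomes). Island intervals are overwritten by a CpG-rich
    generator that emits a CCGG block with the island's density and
    background bases otherwise, giving islands a CpG density well above
    3x background.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = spec.gc_background
    probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])

    genome: dict[str, str] = {}
    for contig, length in spec.contigs:
        seq = rng.choice(_BASES, size=length, p=probs)
        if spec.cpg_depletion > 0:
            is_cg = (seq[:-1] == "C") & (seq[1:] == "G")
            hit = np.flatnonzero(is_cg)
            mutate = hit[rng.random(len(hit)) < spec.cpg_depletion]
            seq[mutate + 1] = rng.choice(np.array(list("AT")), size=len(mutate))
        genome[contig] = "".join(seq)

    for contig, start, end, dens in spec.cpg_islands:
        out: list[str] = []
        n = end - start
        while len(out) < n:
            if rng.random() < dens:
                out.extend("CCGG")
            else:
                out.append(str(rng.choice(_BASES, p=probs)))
        island = "".join(out[:n])
        genome[contig] = genome[contig][:start] + island + genome[contig][end:]

    genes = pd.DataFrame(
        [(c, s, e, f"gene{i}", 0, st) for i, (c, st, s, e) in enumerate(spec.genes)],
        columns=["contig", "start", "end", "name", "score", "strand"],
    )
    islands = pd.DataFrame(
        [(c, s, e, f"island{i}", 0, ".") for i, (c, s, e, _d) in enumerate(spec.cpg_islands)],
        columns=["contig", "start", "end", "name", "score", "strand"],
    )
    return genome, genes, islands


def plant_methylome(catalog: LpnPISiteCatalog, spec: MethylomeSpec) -> Methylome:
    """Assign methylation probabilities to catalog sites per group/replicate.

    Outside planted intervals all group means equal the baseline; inside a
    planted interval the target group's mean is baseline + delta, clipped to
    [0,1]. Planted intervals covering fewer than ``spec.min_sites`` catalog
    sites are warned about and recorded as uncoverable.
    """
    spec.validate()
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    n = len(catalog)
    base = np.full(n, spec.baseline_meth)
    means = {g: base.copy() for g in spec.groups}
    uncoverable = []
    for contig, start, end, group, delta in spec.planted_dmrs:
        ids = catalog.sites_in_interval(contig, start, end)
        if len(ids) < spec.min_sites:
            warnings.warn(
                f"planted interval {contig}:{start}-{end} covers {len(ids)} "
                f"site(s) (< {spec.min_sites}); recorded as uncoverable",
                stacklevel=2,
            )
            uncoverable.append((contig, start, end, group, delta))
            continue
        idx = catalog.sites.index.get_indexer(ids)
        means[group][idx] = np.clip(means[group][idx] + delta, 0.0, 1.0)

    rng = np.random.default_rng(spec.seed)
    reps = {}
    for g, k in spec.groups.items():
        noise = rng.normal(0.0, spec.noise_sd, size=(k, n)) if spec.noise_sd > 0 else 0.0
        reps[g] = np.clip(means[g][None, :] + noise, 0.0, 1.0)
    return Methylome(group_means=means, replicates=reps, uncoverable=uncoverable)


def simulate_reads(
    genome: Mapping[str, str],
    catalog: LpnPISiteCatalog,
    site_probs: np.ndarray,
    cfg: ReadSimConfig,
    sample: str = "sample",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one replicate's MeD-seq reads from per-site methylation.

    Per site the fragment count is Binomial(cfg.depth, probability). Each
    fragment is cfg.fragment_length bp of genomic sequence with the site's
    CpG 'C' at offset 15 or 16 (uniform), emitted forward or
    reverse-complemented with equal probability, then padded 3' with adapter
    to cfg.read_length. Sites too close to a contig edge for a full fragment
    are skipped and logged.

    Returns (reads, truth) where reads are (name, sequence) pairs and truth
    is a per-site table of realized fragment counts.
    """
    cfg.validate()
    if len(site_probs) != len(catalog):
        raise ValueError("site_probs length does not match catalog")
    rng = np.random.default_rng(cfg.seed)
    counts = rng.binomial(cfg.depth, np.clip(site_probs, 0.0, 1.0))

    fill = cfg.adapter[: cfg.read_length - cfg.fragment_length]
    reads: list[tuple[str, str]] = []
    truth_counts = np.zeros(len(catalog), dtype=int)
    skipped = 0
    rows = catalog.sites
    for i, (sid, row) in enumerate(rows.iterrows()):
        c = int(counts[i])
        if c == 0:
            continue
        seq = genome[row.contig]
        pos = int(row.cpg_pos)
        offsets = rng.choice(CPG_FRAGMENT_OFFSETS, size=c)
        flip = rng.random(c) < 0.5
        emitted = 0
        for j in range(c):
            start = pos - int(offsets[j])
            end = start + cfg.fragment_length
            if start < 0 or end > len(seq):
                continue
            frag = seq[start:end]
            if flip[j]:
                frag = reverse_complement(frag)
            reads.append((f"{sample}:site{sid}:{emitted}", frag + fill))
            emitted += 1
        if emitted < c:
            skipped += 1
            log.info("site %s at %s:%d too close to contig edge; %d fragment(s) dropped",
                     sid, row.contig, pos, c - emitted)
        truth_counts[i] = emitted

    truth = pd.DataFrame({
        "site_id": rows.index,
        "contig": rows["contig"].to_numpy(),
        "cpg_pos": rows["cpg_pos"].to_numpy(),
        "count": truth_counts,
    }).set_index("site_id")
    return reads, truth


def simulate_site_counts(
    catalog: LpnPISiteCatalog,
    weights: np.ndarray,
    total_reads: int,
    seed: int,
) -> np.ndarray:
    """Draw per-site counts for one replicate, bypassing FASTQ.

    Counts are multinomial over catalog sites with probabilities proportional
    to ``weights`` (typically methylation probabilities); the draw sums to
    ``total_reads`` exactly.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(catalog):
        raise ValueError("weights length does not match catalog")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if s == 0:
        raise ValueError("all site weights are zero")
    rng = np.random.default_rng(seed)
    return rng.multinomial(total_reads, w / s)


def write_fastq(reads: Sequence[tuple[str, str]], path: str) -> None:
    """Write (name, seq) pairs as FASTQ with uniform maximal quality."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    from Bio import SeqIO
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]
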