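"""End-to-end pipeline driver with YAML configuration and a manifest.

A run executes simulate (optional) -> catalog -> process -> aggregate ->
DMR calling -> clustering and writes every stage output plus a JSON
manifest of parameters and output hashes; a fixed seed reproduces the
manifest bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import medseq.aggregate as agg
from . import catalog as cat
from . import cluster as clu
from . import dmr as dmrmod
from . import io as mio
from . import pipeline as pipe
from . import simulate as sim

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All paths, constants and thresholds of one pipeline run.

    When ``simulate`` is true, the toy genome/reads are generated first and
    the path fields are filled in under ``outdir``; otherwise genome, genes,
    islands and reads must point at existing files.
    """

    outdir: str
    seed: int = 0
    simulate: bool = True
    genome: str | None = None
    genes: str | None = None
    islands: str | None = None
    reads: dict[str, str] = field(default_factory=dict)   # sample -> FASTQ
    groups: dict[str, str] = field(default_factory=dict)  # sample -> group
    motif: str = cat.DEFAULT_MOTIF
    require_cpg: bool = True
    adapter: str = sim.DEFAULT_ADAPTER
    site_window: tuple[int, int] = pipe.SITE_WINDOW
    tss_halfwidth: int = cat.TSS_HALFWIDTH
    thresholds: dmrmod.DMRThresholds = field(default_factory=dmrmod.DMRThresholds)
    # simulation block (used when simulate is true)
    sim_contig_length: int = 60_000
    sim_n_islands: int = 4
    sim_n_genes: int = 3
    sim_groups: dict[str, int] = field(default_factory=lambda: {"grpA": 2, "grpB": 2})
    sim_depth: int = 30
    sim_meth_delta: float = 0.4

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = dmrmod.DMRThresholds(**raw["thresholds"])
        if "site_window" in raw:
            raw["site_window"] = tuple(raw["site_window"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for name in ("genome", "genes", "islands"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(f"config field {name!r} is required when simulate is false")
                if not Path(value).exists():
                    raise ValueError(f"config field {name!r}: path {value} does not exist")
        self.thresholds.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _demo_simulation(cfg: PipelineConfig, out: Path) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Generate the toy study: genome, annotations and per-sample FASTQs."""
    L = cfg.sim_contig_length
    islands = []
    step = L // (cfg.sim_n_islands + 1)
    for i in range(cfg.sim_n_islands):
        s = (i + 1) * step
        islands.append(("chr1", s, s + 800, 0.12))
    genes = []
    gstep = L // (cfg.sim_n_genes + 1)
    for i in range(cfg.sim_n_genes):
        s = (i + 1) * gstep - 2000
        genes.append(("chr1", "+" if i % 2 == 0 else "-", s, s + 4000))
    gspec = sim.ToyGenomeSpec(
        seed=cfg.seed, contigs=[("chr1", L)], gc_background=0.5,
        cpg_islands=islands, genes=genes,
    )
    genome, genes_df, islands_df = sim.make_toy_genome(gspec)
    mio.write_fasta(genome, out / "genome.fa")
    mio.write_bed(genes_df, out / "genes.bed")
    mio.write_bed(islands_df, out / "islands.bed")

    catalog = cat.scan_sites(genome, cfg.motif, cfg.require_cpg)
    target = list(cfg.sim_groups)[0]
    planted = [("chr1", s, s + 800, target, cfg.sim_meth_delta) for (_c, s, _e, _d) in islands[:2]]
    mspec = sim.MethylomeSpec(
        seed=cfg.seed + 1, groups=cfg.sim_groups, baseline_meth=0.2,
        planted_dmrs=planted, noise_sd=0.02,
    )
    methylome = sim.plant_methylome(catalog, mspec)
    truth = pd.DataFrame(planted, columns=["contig", "start", "end", "group", "delta"])
    truth.to_csv(out / "planted_dmrs.tsv", sep="\t", index=False)

    reads_paths = {}
    for k, (sample, _group, probs) in enumerate(methylome.iter_samples()):
        rcfg = sim.ReadSimConfig(seed=cfg.seed + 100 + k, depth=cfg.sim_depth)
        reads, truth_counts = sim.simulate_reads(genome, catalog, probs, rcfg, sample=sample)
        fq = out / f"{sample}.fastq"
        sim.write_fastq(reads, fq)
        truth_counts.to_csv(out / f"{sample}.truth.tsv", sep="\t")
        reads_paths[sample] = str(fq)
        cfg.groups[sample] = _group
    cfg.reads = reads_paths
    return genome, genes_df, islands_df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the JSON manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            genome, genes_df, islands_df = _demo_simulation(config, out)
        else:
            genome = mio.read_fasta(config.genome)
            genes_df = mio.read_bed(config.genes)
            islands_df = mio.read_bed(config.islands)

        stage = "catalog"
        catalog = cat.scan_sites(genome, config.motif, config.require_cpg)
        catalog.to_bed().to_csv(out / "catalog.bed", sep="\t", header=False, index=False)
        lengths = {c: len(s) for c, s in genome.items()}
        regions = cat.build_regions(genes_df, islands_df, lengths, config.tss_halfwidth)
        mio.write_bed(
            regions.regions.rename(columns={"region_id": "name"})
            .assign(score=0)[["contig", "start", "end", "name", "score", "strand"]],
            out / "regions.bed",
        )

        stage = "process"
        matcher = pipe.ExactMatcher(genome)
        tracks = []
        qc = {}
        for sample, fq in config.reads.items():
            reads = sim.read_fastq(fq)
            track = pipe.process_sample(
                reads, matcher, catalog, config.adapter, sample=sample,
                motif=config.motif, window=config.site_window,
            )
            mio.write_bedgraph(track.to_bedgraph(), out / f"{sample}.sites.bedgraph")
            qc[sample] = {
                "input_reads": track.n_input_reads,
                "assigned": track.total_assigned,
                "rejected": track.rejected,
            }
            tracks.append(track)
        (out / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))

        stage = "aggregate"
        table = agg.normalize_rpm(agg.aggregate(tracks, regions, catalog))
        table.counts.to_csv(out / "region_counts.tsv", sep="\t")
        pooled = agg.pool_groups(table, config.groups)

        stage = "dmr"
        group_names = sorted(set(config.groups.values()))
        ga, gb = group_names[0], group_names[1]
        region_dmrs = dmrmod.call_region_dmrs(pooled, ga, gb, config.thresholds)
        region_dmrs.to_csv(out / "dmrs_region.tsv", sep="\t")
        members: dict[str, list[str]] = {}
        for s, g in config.groups.items():
            members.setdefault(g, []).append(s)
        window_dmrs = dmrmod.sliding_window_dmrs(
            tracks, members, ga, gb, catalog, config.thresholds)
        window_dmrs = dmrmod.overlap_annotate(window_dmrs, regions)
        window_dmrs.to_csv(out / "dmrs_window.tsv", sep="\t", index=False)

        stage = "cluster"
        basis = region_dmrs.index if len(region_dmrs) >= 2 else table.counts.index
        z, _const = clu.zscore_rows(table.rpm.loc[basis])
        result = clu.hcluster(z)
        clu.export_dendrogram(result, str(out / "dendrogram.nwk"))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "parameters": {
            "motif": config.motif,
            "site_window": list(config.site_window),
            "tss_halfwidth": config.tss_halfwidth,
            "thresholds": asdict(config.thresholds),
        },
        "n_region_dmrs": int(len(region_dmrs)),
        "n_window_dmrs": int(len(window_dmrs)),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
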