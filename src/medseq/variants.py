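"""Heuristic somatic-variant filtering and mutation-inheritance comparison.

Variant calling itself happens upstream (exome pipeline, Strelka2-style
caller, population-frequency annotation); this module applies the
post-calling heuristic filter — all caller filters passed, at least six
total reads, population allele frequency at most 0.02% — and asks which
somatic mutations observed in parental tubular epithelial cell (TEC) lines
reappear in the iPSC clones reprogrammed from them.

Variant tables use VCF conventions (1-based pos); identity is exact
(contig, pos, ref, alt) match, inputs assumed normalized upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Minimum total read depth to keep a call ("fewer than six total reads" fails).
MIN_DEPTH = 6
#: Maximum population (ExAC) allele frequency, as a fraction: 0.02%.
MAX_POP_AF = 0.0002

REQUIRED_COLUMNS = ["contig", "pos", "ref", "alt", "filter_pass", "depth", "vaf"]


def _check_table(df: pd.DataFrame, extra: Sequence[str] = ()) -> None:
    missing = [c for c in list(REQUIRED_COLUMNS) + list(extra) if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing column(s): {missing}")
    for i, row in df.iterrows():
        if row["ref"] == row["alt"]:
            raise ValueError(f"record {i}: ref equals alt")
        if row["depth"] < 0:
            raise ValueError(f"record {i}: negative depth")
        if not 0.0 <= row["vaf"] <= 1.0:
            raise ValueError(f"record {i}: VAF outside [0,1]")


def heuristic_filter(
    variants: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    max_pop_af: float = MAX_POP_AF,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain calls passing all caller filters, depth and population-AF gates.

    A record is kept iff filter_pass is true AND depth >= min_depth AND
    pop_af <= max_pop_af. Missing pop_af means the variant is absent from
    the population database and is treated as 0 (novel variants are never
    rejected for novelty). Rejection reasons are tallied by the first
    failing rule, in the order caller_filter, depth, pop_af.
    """
    _check_table(variants)
    pop = variants["pop_af"] if "pop_af" in variants.columns else pd.Series(0.0, index=variants.index)
    pop = pop.fillna(0.0)
    reasons = {"caller_filter": 0, "depth": 0, "pop_af": 0}
    keep = []
    for i, row in variants.iterrows():
        if not bool(row["filter_pass"]):
            reasons["caller_filter"] += 1
        elif row["depth"] < min_depth:
            reasons["depth"] += 1
        elif pop[i] > max_pop_af:
            reasons["pop_af"] += 1
        else:
            keep.append(i)
    return variants.loc[keep].copy(), reasons


def exonic_nonsyn_filter(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep exonic, non-synonymous calls.

    Requires ``region_class`` (e.g. exonic/intronic/intergenic) and
    ``consequence`` annotation columns produced upstream.
    """
    for col in ("region_class", "consequence"):
        if col not in variants.columns:
            raise ValueError(f"missing annotation column {col!r}")
    mask = (variants["region_class"] == "exonic") & (variants["consequence"] != "synonymous")
    return variants[mask].copy()


_KEY = ["contig", "pos", "ref", "alt"]


def _keyed(df: pd.DataFrame) -> pd.DataFrame:
    return df.set_index(pd.MultiIndex.from_frame(df[_KEY]))


def compare_inheritance(
    tec_variants: Mapping[str, pd.DataFrame],
    ipsc_variants: Mapping[str, pd.DataFrame],
    lineage: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Which TEC somatic mutations survive reprogramming into iPSC clones?

    Rows are the (filtered) somatic variants of each parental TEC line;
    columns hold the VAF of that variant in the TEC line and in each derived
    clone, NaN when absent (absence is distinct from VAF 0). Per line,
    variants are classified by how many derived clones carry them: "all",
    "some" or "none"; the classes partition the rows.
    """
    unknown = [c for c, parent in lineage.items() if parent not in tec_variants]
    if unknown:
        raise ValueError(f"clone(s) with unknown parental TEC line: {unknown}")
    clones_of: dict[str, list[str]] = {}
    for clone in ipsc_variants:
        if clone not in lineage:
            raise ValueError(f"clone {clone!r} missing from lineage map")
        clones_of.setdefault(lineage[clone], []).append(clone)

    rows = []
    summary_rows = []
    for line, tv in tec_variants.items():
        tv = _keyed(tv)
        clones = sorted(clones_of.get(line, []))
        clone_tables = {c: _keyed(ipsc_variants[c]) for c in clones}
        n_all = n_some = n_none = 0
        for key, rec in tv.iterrows():
            vals = {"tec_line": line, "contig": key[0], "pos": key[1],
                    "ref": key[2], "alt": key[3], f"vaf_{line}": rec["vaf"]}
            present = 0
            for c in clones:
                if key in clone_tables[c].index:
                    vals[f"vaf_{c}"] = float(clone_tables[c].loc[key, "vaf"])
                    present += 1
                else:
                    vals[f"vaf_{c}"] = np.nan
            if clones and present == len(clones):
                cls = "all"
                n_all += 1
            elif present > 0:
                cls = "some"
                n_some += 1
            else:
                cls = "none"
                n_none += 1
            vals["inheritance"] = cls
            rows.append(vals)
        summary_rows.append((line, len(tv), n_all, n_some, n_none))

    table = pd.DataFrame(rows)
    summary = pd.DataFrame(
        summary_rows, columns=["tec_line", "n_variants", "all", "some", "none"]
    )
    return table, summary


@dataclass
class VariantFixtureSpec:
    """Planted sharing structure for synthetic variant tables."""

    seed: int
    n_shared: int = 2          # TEC variants present in every derived clone
    n_partial: int = 0         # TEC variants present in a strict subset of clones
    n_private_tec: int = 3     # TEC-only variants
    n_private_ipsc: int = 2    # clone-only variants (never rows of the table)
    clones: tuple[str, ...] = ("cloneA", "cloneB")
    tec_line: str = "TEC1"
    tec_vaf_range: tuple[float, float] = (0.05, 0.45)
    ipsc_vaf_range: tuple[float, float] = (0.3, 0.7)


def make_variant_fixture(
    spec: VariantFixtureSpec,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], dict[str, str]]:
    """Deterministic synthetic TEC/iPSC variant tables with known sharing.

    Emulates the low-VAF heterogeneous somatic spectrum of primary cyst
    epithelium versus the higher VAFs of clonal iPSC lines. Returns
    (tec_variants, ipsc_variants, lineage) ready for compare_inheritance.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))

    def new_variant(i: int) -> dict:
        ref, alt = rng.choice(bases, size=2, replace=False)
        return {"contig": "chr1", "pos": 1000 + 10 * i, "ref": str(ref),
                "alt": str(alt), "filter_pass": True, "depth": int(rng.integers(20, 200)),
                "pop_af": 0.0}

    counter = 0
    def take(n: int) -> list[dict]:
        nonlocal counter
        out = [new_variant(counter + j) for j in range(n)]
        counter += n
        return out

    shared = take(spec.n_shared)
    partial = take(spec.n_partial)
    tec_only = take(spec.n_private_tec)

    def with_vaf(recs: list[dict], lohi: tuple[float, float]) -> list[dict]:
        return [dict(r, vaf=float(rng.uniform(*lohi))) for r in recs]

    tec = pd.DataFrame(with_vaf(shared + partial + tec_only, spec.tec_vaf_range))

    ipsc: dict[str, pd.DataFrame] = {}
    for k, clone in enumerate(spec.clones):
        recs = list(shared)
        if partial and len(spec.clones) > 1:
            # strict subset: only the first clone carries the partial set
            if k == 0:
                recs += partial
        recs = recs + take(spec.n_private_ipsc)
        ipsc[clone] = pd.DataFrame(with_vaf(recs, spec.ipsc_vaf_range))

    lineage = {clone: spec.tec_line for clone in spec.clones}
    return {spec.tec_line: tec}, ipsc, lineage


def read_variant_table(path: str, info_keys: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Load a variant table from TSV or VCF.

    TSV files must already carry the required columns. For VCF, per-record
    INFO fields are mapped onto columns via ``info_keys`` (defaults: DP ->
    depth, AF -> vaf, POP_AF -> pop_af); FILTER PASS/'.' sets filter_pass.
    """
    if str(path).endswith((".tsv", ".txt", ".csv")):
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep)
        _check_table(df)
        return df

    import pysam

    keys = {"depth": "DP", "vaf": "AF", "pop_af": "POP_AF"}
    keys.update(info_keys or {})
    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            flt = list(rec.filter.keys())
            passed = flt in ([], ["PASS"])
            for alt in rec.alts or ():
                info = dict(rec.info)
                def scalar(v):
                    return v[0] if isinstance(v, tuple) else v
                rows.append({
                    "contig": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt,
                    "filter_pass": passed,
                    "depth": int(scalar(info.get(keys["depth"], 0))),
                    "vaf": float(scalar(info.get(keys["vaf"], 0.0))),
                    "pop_af": float(scalar(info[keys["pop_af"]])) if keys["pop_af"] in info else np.nan,
                })
    df = pd.DataFrame(rows)
    _check_table(df)
    return df
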