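"""Light wrappers for the plain-text formats the pipeline exchanges."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    """BED with 3-6 columns -> DataFrame; raises with the offending line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            rows.append({
                "contig": parts[0], "start": start, "end": end,
                "name": parts[3] if len(parts) > 3 else "",
                "score": parts[4] if len(parts) > 4 else 0,
                "strand": parts[5] if len(parts) > 5 else ".",
            })
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bedgraph(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
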