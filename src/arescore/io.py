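"""Sequence and table I/O, and the per-gene transcript collapsing rule.

FASTA reading/writing is delegated to Bio.SeqIO; tables are plain TSV read
with pandas. For transcriptome-wide analyses where several transcripts map
to the same gene locus, only the transcript with the highest score per gene
is kept (`collapse_by_gene`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import SequenceRecord

__all__ = [
    "UtrTableRow",
    "read_fasta",
    "write_fasta",
    "read_utr_table",
    "collapse_by_gene",
    "read_time_courses",
]


@dataclass(frozen=True)
class UtrTableRow:
    gene_id: str
    transcript_id: str
    seq: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, preserving record order.

    The id is the header token up to the first whitespace; wrapped sequence
    lines are concatenated. A file whose first non-blank line is not a
    header is rejected with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: sequence data before first FASTA header"
                    )
                break
    return [
        SequenceRecord(rec.id, str(rec.seq).strip())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with lines wrapped at ``width`` characters."""
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_utr_table(path: str | Path) -> list[UtrTableRow]:
    """Read a TSV with columns gene_id, transcript_id, seq.

    Blank lines are skipped; transcript ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, skip_blank_lines=True)
    required = {"gene_id", "transcript_id", "seq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    dup = df["transcript_id"][df["transcript_id"].duplicated()].unique()
    if dup.size:
        raise ValueError(f"{path}: duplicate transcript_id: {', '.join(dup)}")
    df = df.fillna({"seq": ""})
    return [
        UtrTableRow(r.gene_id, r.transcript_id, r.seq)
        for r in df.itertuples(index=False)
    ]


def collapse_by_gene(scored: Sequence[tuple[str, str, float]]) -> list[tuple[str, str, float]]:
    """Keep, per gene, the transcript with the highest score.

    Input triples are (gene_id, transcript_id, score). Ties are broken by
    the lexicographically smallest transcript_id so the result is
    reproducible. Output is ordered by first appearance of each gene.
    """
    best: dict[str, tuple[str, str, float]] = {}
    for gene_id, transcript_id, score in scored:
        cur = best.get(gene_id)
        if (
            cur is None
            or score > cur[2]
            or (score == cur[2] and transcript_id < cur[1])
        ):
            best[gene_id] = (gene_id, transcript_id, score)
    return list(best.values())


def read_time_courses(path: str | Path) -> dict[str, "pd.DataFrame"]:
    """Read decay time courses from a TSV with columns id, time_min, abundance.

    Returns one (time_min, abundance) frame per transcript id, sorted by time.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"id", "time_min", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    return {
        str(tid): g[["time_min", "abundance"]].sort_values("time_min").reset_index(drop=True)
        for tid, g in df.groupby("id", sort=False)
    }
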