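"""Transcript container with 5'UTR/CDS/3'UTR boundaries and FASTA/table IO.

Coordinates are 0-based half-open throughout: the 5'UTR is ``[0, utr5_end)``,
the CDS ``[utr5_end, cds_end)`` and the 3'UTR ``[cds_end, length)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGIONS = ("5UTR", "CDS", "3UTR")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    sequence: str
    utr5_end: int
    cds_end: int

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (0 <= self.utr5_end <= self.cds_end <= n):
            raise ValueError(
                f"{self.transcript_id}: invalid region boundaries "
                f"(utr5_end={self.utr5_end}, cds_end={self.cds_end}, length={n})"
            )
        if self.cds_end == self.utr5_end:
            raise ValueError(f"{self.transcript_id}: empty CDS")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region_bounds(self, region: str) -> tuple[int, int]:
        if region == "5UTR":
            return 0, self.utr5_end
        if region == "CDS":
            return self.utr5_end, self.cds_end
        if region == "3UTR":
            return self.cds_end, self.length
        raise ValueError(f"unknown region {region!r}")

    def region_of(self, position: int) -> str:
        """Region label for a transcript position (hits are assigned by start)."""
        if not 0 <= position < self.length:
            raise ValueError(f"position {position} outside [0, {self.length})")
        if position < self.utr5_end:
            return "5UTR"
        if position < self.cds_end:
            return "CDS"
        return "3UTR"


def write_fasta(transcripts: list[Transcript], path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcripts
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_region_table(transcripts: list[Transcript], path) -> None:
    df = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "utr5_end": [t.utr5_end for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
            "length": [t.length for t in transcripts],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_transcripts(fasta_path, table_path) -> list[Transcript]:
    """Load transcripts from a FASTA plus a region-boundary table (TSV).

    The table needs columns transcript_id, utr5_end, cds_end; a length column,
    if present, is validated against the sequence length.
    """
    table = pd.read_csv(table_path, sep="\t")
    required = {"transcript_id", "utr5_end", "cds_end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    bounds = table.set_index("transcript_id")
    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in bounds.index:
            raise ValueError(f"transcript {rec.id} absent from region table")
        row = bounds.loc[rec.id]
        seq = str(rec.seq)
        if "length" in bounds.columns and int(row["length"]) != len(seq):
            raise ValueError(
                f"{rec.id}: table length {int(row['length'])} != sequence length {len(seq)}"
            )
        transcripts.append(
            Transcript(rec.id, seq, int(row["utr5_end"]), int(row["cds_end"]))
        )
    return transcripts
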