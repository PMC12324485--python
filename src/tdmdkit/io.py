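"""FASTA helpers for transcriptomes (sense-strand DNA)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import to_dna


def write_transcript_fasta(transcripts: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=tid, description="") for tid, seq in transcripts.items()),
        str(path),
        "fasta",
    )


def read_transcript_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
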