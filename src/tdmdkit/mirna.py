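"""miRNA records and the miRNA database FASTA format.

Database headers carry the strand role and family as tokens, e.g.::

    >mirf-03 guide family=mir35fam context=ACGGUU...

``context=`` is the genomic sequence immediately 3' of the miRNA locus,
needed to distinguish templated 3' extensions from untemplated tails in
isomiR analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import check_rna, to_rna


@dataclass(frozen=True)
class MiRNARecord:
    """A mature small RNA (guide or passenger strand) with annotation."""

    id: str
    sequence: str  # RNA, 5'->3'
    role: str  # "guide" | "passenger"
    family_id: str
    downstream_context: str = ""  # genomic sequence 3' of the locus (RNA)

    def __post_init__(self) -> None:
        check_rna(self.sequence, f"miRNA {self.id}")
        if len(self.sequence) < 18:
            raise ValueError(f"miRNA {self.id}: sequence shorter than 18 nt")
        if self.role not in ("guide", "passenger"):
            raise ValueError(f"miRNA {self.id}: role must be guide|passenger")

    @property
    def canonical_length(self) -> int:
        return len(self.sequence)

    @property
    def seed(self) -> str:
        """Positions 2-8 from the 5' end."""
        return self.sequence[1:8]


def guides(records: list[MiRNARecord]) -> list[MiRNARecord]:
    return [r for r in records if r.role == "guide"]


def family_map(records: list[MiRNARecord]) -> dict[str, str]:
    """guide id -> family id."""
    return {r.id: r.family_id for r in records if r.role == "guide"}


def write_mirna_fasta(records: list[MiRNARecord], path: str | Path) -> None:
    seqs = []
    for r in records:
        desc = f"{r.role} family={r.family_id}"
        if r.downstream_context:
            desc += f" context={r.downstream_context}"
        seqs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(seqs, str(path), "fasta")


def read_mirna_fasta(path: str | Path) -> list[MiRNARecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split()[1:]
        role = "guide"
        family = ""
        context = ""
        for f in fields:
            if f in ("guide", "passenger"):
                role = f
            elif f.startswith("family="):
                family = f.split("=", 1)[1]
            elif f.startswith("context="):
                context = to_rna(f.split("=", 1)[1])
        out.append(
            MiRNARecord(
                id=rec.id,
                sequence=to_rna(str(rec.seq)),
                role=role,
                family_id=family,
                downstream_context=context,
            )
        )
    return out
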