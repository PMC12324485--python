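"""Small nucleotide-alphabet helpers shared across modules.

All miRNA sequences are handled as RNA (``ACGU``) and transcript/read
sequences as DNA (``ACGT``); these helpers convert at module boundaries.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_RNA_COMP = str.maketrans("ACGU", "UGCA")
_DNA_COMP = str.maketrans("ACGT", "TGCA")

# Watson-Crick partners, RNA alphabet.
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def pair_kind(a: str, b: str) -> str | None:
    """Classify an (RNA, RNA) base pair: 'WC', 'GU' or None."""
    if (a, b) in _WC:
        return "WC"
    if (a, b) in _GU:
        return "GU"
    return None


def check_rna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq or set(seq) - RNA_ALPHABET:
        raise ValueError(f"{what} must be non-empty RNA (ACGU), got {seq!r}")
    return seq
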