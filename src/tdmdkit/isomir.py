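"""3' isomiR decomposition: trimming, tailing, and genotype comparison.

Reads are assigned to a miRNA by an exact 5' anchor and decomposed against
the *templated* reference — the canonical miRNA followed by its downstream
genomic context — by greedy maximal prefix matching. Whatever matches the
template is templated sequence (trimming is canonical length minus templated
length); the remaining 3' suffix is an untemplated tail. A tail nucleotide
that coincides with the next templated base is absorbed into the template by
maximality; such reads are indistinguishable from templated variants and the
decomposition is therefore conservative about calling tails.

5' isomiRs are out of scope: a read whose first ``anchor_len`` nucleotides
differ from the canonical 5' end is reported as unassigned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from ._seq import to_rna
from .mirna import MiRNARecord

ISO_CLASSES = ("canonical", "trimmed", "tailed", "trimmed_tailed")


@dataclass(frozen=True)
class IsoformRecord:
    mirna_id: str
    read_seq: str
    templated_len: int
    trim_len: int
    tail_seq: str
    iso_class: str  # canonical | trimmed | tailed | trimmed_tailed | unassigned
    templated_extension: bool = False


@dataclass(frozen=True)
class IsoformProfile:
    mirna_id: str
    sample_id: str
    n_reads: int  # assigned reads
    n_unassigned: int
    fractions: dict[str, float]  # over assigned reads, sums to 1
    mean_trim_len: float  # among reads with trim_len > 0 (nan if none)
    tail_composition: dict[str, float]  # per-nt frequency over tail positions

    def metric(self, which: str) -> float:
        """Fraction trimmed or tailed (trimmed_tailed counts toward both)."""
        if which not in ("trimmed", "tailed"):
            raise ValueError("metric must be 'trimmed' or 'tailed'")
        return self.fractions[which] + self.fractions["trimmed_tailed"]


def decompose_read(
    read: str,
    canonical: str,
    context: str,
    mirna_id: str = "",
    anchor_len: int = 14,
    max_tail_len: int = 5,
) -> IsoformRecord:
    """Core decomposition of a read against canonical + downstream context.

    The templated length is the longest read prefix matching the templated
    reference; the remainder is the untemplated tail. The record is
    ``unassigned`` when the 5' anchor mismatches or the tail exceeds
    ``max_tail_len``, but its (templated_len, tail) decomposition is still
    reported, so templated_len + |tail| = |read| holds for every record.
    """
    read = to_rna(read)
    if len(read) < anchor_len:
        raise ValueError(f"read shorter than anchor_len={anchor_len}")
    if not context:
        raise ValueError(f"miRNA {mirna_id or canonical} lacks downstream context")
    template = canonical + context
    t = 0
    while t < len(read) and t < len(template) and read[t] == template[t]:
        t += 1
    tail = read[t:]
    if read[:anchor_len] != canonical[:anchor_len] or len(tail) > max_tail_len:
        return IsoformRecord(mirna_id, read, t, 0, tail, "unassigned")
    trim = max(0, len(canonical) - t)
    ext = t > len(canonical)
    if trim == 0 and not tail:
        cls = "canonical"
    elif trim > 0 and not tail:
        cls = "trimmed"
    elif trim == 0:
        cls = "tailed"
    else:
        cls = "trimmed_tailed"
    return IsoformRecord(mirna_id, read, t, trim, tail, cls, templated_extension=ext)


def assign_isoform(
    read_seq: str,
    mirna: MiRNARecord,
    anchor_len: int = 14,
    max_tail_len: int = 5,
) -> IsoformRecord:
    """Decompose one read against a miRNA's templated reference."""
    return decompose_read(
        read_seq,
        mirna.sequence,
        mirna.downstream_context,
        mirna_id=mirna.id,
        anchor_len=anchor_len,
        max_tail_len=max_tail_len,
    )


def profile_isoforms(
    records: list[IsoformRecord], sample_id: str = ""
) -> list[IsoformProfile]:
    """Per-miRNA isoform-class fractions over assigned reads."""
    if not records:
        raise ValueError("no isoform records to profile")
    by_mirna: dict[str, list[IsoformRecord]] = {}
    for r in records:
        by_mirna.setdefault(r.mirna_id, []).append(r)
    out = []
    for mid in sorted(by_mirna):
        rs = by_mirna[mid]
        assigned = [r for r in rs if r.iso_class != "unassigned"]
        n = len(assigned)
        counts = Counter(r.iso_class for r in assigned)
        fractions = {c: counts.get(c, 0) / n if n else 0.0 for c in ISO_CLASSES}
        trims = [r.trim_len for r in assigned if r.trim_len > 0]
        tail_nt = Counter()
        for r in assigned:
            tail_nt.update(r.tail_seq)
        total_tail = sum(tail_nt.values())
        comp = {
            nt: tail_nt.get(nt, 0) / total_tail if total_tail else 0.0
            for nt in "ACGU"
        }
        out.append(
            IsoformProfile(
                mirna_id=mid,
                sample_id=sample_id,
                n_reads=n,
                n_unassigned=len(rs) - n,
                fractions=fractions,
                mean_trim_len=float(np.mean(trims)) if trims else float("nan"),
                tail_composition=comp,
            )
        )
    return out


def compare_profiles(
    profiles_a: list[IsoformProfile],
    profiles_b: list[IsoformProfile],
    metric: str = "trimmed",
    min_reads: int = 50,
) -> pd.DataFrame:
    """Two-proportion z-test of an isoform metric between two sample groups.

    Positive ``delta`` means a higher fraction in group b. p-values are
    two-sided with the pooled-proportion standard error; q is
    Benjamini-Hochberg across miRNAs. miRNAs with fewer than ``min_reads``
    assigned reads in either group are flagged ``low_power`` (still tested).
    """
    if metric not in ("trimmed", "tailed"):
        raise ValueError("metric must be 'trimmed' or 'tailed'")
    a = {p.mirna_id: p for p in profiles_a}
    b = {p.mirna_id: p for p in profiles_b}
    rows = []
    for mid in sorted(set(a) & set(b)):
        pa, pb = a[mid], b[mid]
        fa, fb = pa.metric(metric), pb.metric(metric)
        na, nb = pa.n_reads, pb.n_reads
        pooled = (fa * na + fb * nb) / (na + nb)
        se = np.sqrt(pooled * (1 - pooled) * (1 / na + 1 / nb))
        z = (fb - fa) / se if se > 0 else 0.0
        p = 2 * norm.sf(abs(z)) if se > 0 else 1.0
        rows.append((mid, fa, fb, fb - fa, z, p, min(na, nb) < min_reads))
    df = pd.DataFrame(
        rows,
        columns=["mirna", "frac_a", "frac_b", "delta", "z", "p", "low_power"],
    ).set_index("mirna")
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df
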