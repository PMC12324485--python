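"""Chimeric eCLIP read preprocessing, hybrid calling, and site clustering.

A hybrid (chimeric) read carries a full-length miRNA ligated to a fragment of
its bound target; identifying both arms reveals the interaction partner.
Processing order follows the small-RNA convention of collapsing exact PCR
duplicates *before* removing the terminal UMIs, so molecules sharing an
insert but differing in UMI remain distinct.

Coordinates are 0-based half-open on the transcript sense strand throughout.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import to_dna
from .mirna import MiRNARecord, guides

REJECTION_REASONS = (
    "no_mirna_arm",
    "target_too_short",
    "ambiguous_target",
    "multiple_mirna_arms",
)


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True)
class ProcessedRead:
    read_id: str
    sequence: str  # DNA
    multiplicity: int  # collapsed exact duplicates


@dataclass(frozen=True)
class HybridRead:
    read_id: str
    mirna_id: str
    mirna_span_in_read: tuple[int, int]
    transcript_id: str
    target_span_on_transcript: tuple[int, int]
    arm_order: str  # "mirna_first" | "target_first"


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


@dataclass(frozen=True)
class BindingSite:
    transcript_id: str
    site_id: str
    span: tuple[int, int]
    summit: int
    member_ids: tuple[str, ...]


@dataclass
class HybridTable:
    """Per-sample (miRNA, transcript, site) counts normalized to RPM.

    RPM is reads per million *total hybrids* in the sample, so the rpm
    column sums to 1e6 per sample.
    """

    frame: pd.DataFrame  # sample, mirna, transcript, site, start, end, count, rpm
    sample_id: str
    total_hybrids: int

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HybridTable":
        frame = pd.read_csv(path, sep="\t")
        return cls(
            frame=frame,
            sample_id=str(frame["sample"].iloc[0]),
            total_hybrids=int(frame["count"].sum()),
        )


# ---------------------------------------------------------------------------
# preprocessing


def _iter_reads(reads) -> list[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        out = []
        with opener(path, "rt") as fh:
            try:
                for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                    out.append((rec.id, to_dna(str(rec.seq))))
            except ValueError as exc:
                raise FastqParseError(
                    f"malformed FASTQ record at index {len(out)}: {exc}"
                ) from exc
        return out
    return [(rid, to_dna(seq)) for rid, seq in reads]


def preprocess_reads(
    reads,
    adapter3: str,
    umi_len: int = 4,
    min_len: int = 18,
) -> tuple[list[ProcessedRead], dict[str, int]]:
    """Adapter-trim, collapse duplicates, strip UMIs, length-filter.

    ``reads`` is a FASTQ(.gz) path or an iterable of (id, sequence). Steps,
    in order: (1) trim at the first occurrence of ``adapter3`` (everything
    from the adapter on is removed); (2) collapse exact duplicate sequences
    to one representative, recording multiplicity; (3) remove ``umi_len`` nt
    from both ends; (4) drop reads shorter than ``min_len``. Returns the
    surviving reads and a log of read counts after each step.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if umi_len < 0:
        raise ValueError("umi_len must be >= 0")
    items = _iter_reads(reads)
    log = {"input": len(items)}

    adapter3 = to_dna(adapter3)
    trimmed = []
    for rid, seq in items:
        k = seq.find(adapter3)
        trimmed.append((rid, seq[:k] if k >= 0 else seq))
    log["adapter_trimmed"] = len(trimmed)

    first_id: dict[str, str] = {}
    mult: Counter[str] = Counter()
    order: list[str] = []
    for rid, seq in trimmed:
        if seq not in mult:
            first_id[seq] = rid
            order.append(seq)
        mult[seq] += 1
    log["collapsed"] = len(order)

    out = []
    for seq in order:
        core = seq[umi_len : len(seq) - umi_len] if umi_len else seq
        if len(core) >= min_len:
            out.append(ProcessedRead(first_id[seq], core, mult[seq]))
    log["umi_removed"] = len(order)
    log["length_filtered"] = len(out)
    return out, log


# ---------------------------------------------------------------------------
# hybrid detection


class TranscriptIndex:
    """Exact k-mer index over a transcriptome for ungapped fragment mapping."""

    def __init__(self, transcripts: dict[str, str], k: int = 12):
        self.k = k
        self.transcripts = {tid: to_dna(seq) for tid, seq in transcripts.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for tid, seq in self.transcripts.items():
            for p in range(len(seq) - k + 1):
                self._index[seq[p : p + k]].append((tid, p))

    def map_fragment(self, frag: str) -> tuple[tuple[str, int] | None, str]:
        """Map a fragment to a unique transcript locus.

        Candidate loci come from k-mer seeding at every fragment offset;
        each is scored by ungapped match count over the full fragment. The
        best locus must beat the second best by >= 2 matches to count as
        unique. Returns ((transcript_id, start), "unique") or (None, reason)
        with reason in {"unmapped", "ambiguous"}.
        """
        k = self.k
        if len(frag) < k:
            return None, "unmapped"
        loci: set[tuple[str, int]] = set()
        for o in range(len(frag) - k + 1):
            for tid, p in self._index.get(frag[o : o + k], ()):
                start = p - o
                if start >= 0 and start + len(frag) <= len(self.transcripts[tid]):
                    loci.add((tid, start))
        if not loci:
            return None, "unmapped"
        scored = []
        for tid, start in sorted(loci):
            ref = self.transcripts[tid][start : start + len(frag)]
            scored.append((sum(a == b for a, b in zip(frag, ref)), tid, start))
        scored.sort(reverse=True)
        if len(scored) > 1 and scored[0][0] - scored[1][0] < 2:
            return None, "ambiguous"
        _, tid, start = scored[0]
        return (tid, start), "unique"


def _find_mirna_arms(
    seq: str, guide_records: list[MiRNARecord], max_mismatches: int
) -> list[tuple[int, int, str, int]]:
    """All full-length guide occurrences: (start, end, guide_id, n_mismatch)."""
    hits = []
    for g in guide_records:
        arm = to_dna(g.sequence)
        L = len(arm)
        if max_mismatches == 0:
            p = seq.find(arm)
            while p >= 0:
                hits.append((p, p + L, g.id, 0))
                p = seq.find(arm, p + 1)
        else:
            for p in range(len(seq) - L + 1):
                mm = sum(a != b for a, b in zip(seq[p : p + L], arm))
                if mm <= max_mismatches:
                    hits.append((p, p + L, g.id, mm))
    return hits


def detect_hybrid(
    read: ProcessedRead | tuple[str, str],
    mirna_db: list[MiRNARecord],
    transcript_index: TranscriptIndex,
    max_mirna_mismatches: int = 0,
    min_target_len: int = 16,
) -> HybridRead | Rejection:
    """Split a processed read into a miRNA arm and a uniquely-mapped target.

    The highest-scoring (fewest-mismatch) full-length guide occurrence is
    the miRNA arm; passenger strands are not searched. The flanking
    remainder of length >= ``min_target_len`` must map uniquely (see
    :meth:`TranscriptIndex.map_fragment`); when both flanks qualify, the
    longer one is tried first. Reads with two disjoint full-length miRNA
    occurrences are rejected as ``multiple_mirna_arms``.
    """
    gds = guides(mirna_db)
    if not gds:
        raise ValueError("miRNA database contains no guide strands")
    rid, seq = (read.read_id, read.sequence) if isinstance(read, ProcessedRead) else read
    seq = to_dna(seq)

    hits = _find_mirna_arms(seq, gds, max_mirna_mismatches)
    if not hits:
        return Rejection(rid, "no_mirna_arm")
    hits.sort(key=lambda h: (h[3], h[0]))
    best = hits[0]
    for other in hits[1:]:
        if other[0] >= best[1] or other[1] <= best[0]:  # disjoint occurrence
            return Rejection(rid, "multiple_mirna_arms")
    start, end, mirna_id, _ = best

    flanks = []
    if start >= min_target_len:
        flanks.append((seq[:start], "left"))
    if len(seq) - end >= min_target_len:
        flanks.append((seq[end:], "right"))
    if not flanks:
        return Rejection(rid, "target_too_short")
    flanks.sort(key=lambda f: len(f[0]), reverse=True)
    for frag, side in flanks:
        locus, status = transcript_index.map_fragment(frag)
        if status == "unique":
            tid, tstart = locus
            return HybridRead(
                read_id=rid,
                mirna_id=mirna_id,
                mirna_span_in_read=(start, end),
                transcript_id=tid,
                target_span_on_transcript=(tstart, tstart + len(frag)),
                arm_order="target_first" if side == "left" else "mirna_first",
            )
    return Rejection(rid, "ambiguous_target")


# ---------------------------------------------------------------------------
# site clustering and tabulation


def cluster_binding_sites(
    hybrids: list[HybridRead], min_overlap: int = 1
) -> list[BindingSite]:
    """Single-linkage clustering of target spans on one transcript.

    Spans overlapping by >= ``min_overlap`` nt join one site; the site span
    is the union and the summit the (leftmost) position of maximal per-base
    fragment coverage.
    """
    if not hybrids:
        return []
    tids = {h.transcript_id for h in hybrids}
    if len(tids) > 1:
        raise ValueError("hybrids must share one transcript_id")
    tid = tids.pop()
    spans = sorted(h.target_span_on_transcript for h in hybrids)
    clusters: list[list[tuple[int, int]]] = [[spans[0]]]
    cur_end = spans[0][1]
    for s, e in spans[1:]:
        if min(cur_end, e) - s >= min_overlap:
            clusters[-1].append((s, e))
            cur_end = max(cur_end, e)
        else:
            clusters.append([(s, e)])
            cur_end = e
    sites = []
    for members in clusters:
        s0 = min(s for s, _ in members)
        e0 = max(e for _, e in members)
        cov = [0] * (e0 - s0)
        for s, e in members:
            for p in range(s - s0, e - s0):
                cov[p] += 1
        summit = s0 + cov.index(max(cov))
        ids = tuple(
            sorted(
                {
                    h.mirna_id
                    for h in hybrids
                    if s0 < h.target_span_on_transcript[1]
                    and h.target_span_on_transcript[0] < e0
                }
            )
        )
        sites.append(
            BindingSite(tid, f"{tid}:{s0}-{e0}", (s0, e0), summit, ids)
        )
    return sites


def cluster_all_sites(
    hybrids: list[HybridRead], min_overlap: int = 1
) -> dict[str, list[BindingSite]]:
    by_tid: dict[str, list[HybridRead]] = defaultdict(list)
    for h in hybrids:
        by_tid[h.transcript_id].append(h)
    return {
        tid: cluster_binding_sites(hs, min_overlap) for tid, hs in by_tid.items()
    }


def tabulate_hybrids(
    hybrids: list[HybridRead],
    sample_id: str,
    sites: dict[str, list[BindingSite]] | None = None,
) -> HybridTable:
    """Count hybrids per (miRNA, transcript, site) and normalize to RPM.

    ``sites`` may be supplied (e.g. clustered on hybrids pooled across
    samples) so that site definitions are consistent between samples;
    otherwise sites are clustered from these hybrids alone.
    """
    if not hybrids:
        raise ValueError("no accepted hybrids to tabulate")
    if sites is None:
        sites = cluster_all_sites(hybrids)
    rows: Counter[tuple] = Counter()
    for h in hybrids:
        site = None
        for cand in sites.get(h.transcript_id, []):
            s, e = cand.span
            hs, he = h.target_span_on_transcript
            if hs < e and s < he:
                site = cand
                break
        if site is None:  # span outside the shared site set: its own site
            hs, he = h.target_span_on_transcript
            site = BindingSite(
                h.transcript_id, f"{h.transcript_id}:{hs}-{he}", (hs, he), hs, (h.mirna_id,)
            )
        rows[(h.mirna_id, h.transcript_id, site.site_id, site.span)] += 1
    total = len(hybrids)
    frame = pd.DataFrame(
        [
            (sample_id, m, t, sid, span[0], span[1], c, c / total * 1e6)
            for (m, t, sid, span), c in sorted(rows.items())
        ],
        columns=["sample", "mirna", "transcript", "site", "start", "end", "count", "rpm"],
    )
    return HybridTable(frame=frame, sample_id=sample_id, total_hybrids=total)


def call_sample(
    reads,
    mirna_db: list[MiRNARecord],
    transcript_index: TranscriptIndex,
    sample_id: str,
    adapter3: str,
    umi_len: int = 4,
    min_len: int = 18,
    max_mirna_mismatches: int = 0,
    min_target_len: int = 16,
) -> tuple[list[HybridRead], list[Rejection], dict[str, int]]:
    """FASTQ -> accepted hybrids for one sample (preprocess + detect)."""
    processed, log = preprocess_reads(reads, adapter3, umi_len, min_len)
    hybrids: list[HybridRead] = []
    rejections: list[Rejection] = []
    for read in processed:
        res = detect_hybrid(
            read, mirna_db, transcript_index, max_mirna_mismatches, min_target_len
        )
        (hybrids if isinstance(res, HybridRead) else rejections).append(res)
    log["hybrids"] = len(hybrids)
    return hybrids, rejections, log
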