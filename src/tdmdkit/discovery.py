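"""Ranking candidate TDMD triggers by hybrid enrichment.

A TDMD trigger is expected to accumulate miRNA hybrids in a decay-deficient
genotype (the trigger-miRISC complex is stabilized when Argonaute turnover is
lost), so candidate interactions are ranked by mean-RPM enrichment of the
mutant over wild type after an abundance filter, and aggregated per binding
site across all members of a miRNA seed family.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .chimera import HybridTable


@dataclass(frozen=True)
class EnrichmentRecord:
    mirna_id: str
    transcript_id: str
    site_id: str
    mean_rpm_wt: float
    mean_rpm_mut: float
    enrichment: float
    passes_abundance: bool
    n_wt: int
    n_mut: int


@dataclass(frozen=True)
class TriggerCandidate:
    transcript_id: str
    site_id: str
    family_id: str
    member_coverage: float
    aggregate_enrichment: float
    rank: int


@dataclass
class RankedReport:
    records: list[EnrichmentRecord]  # abundance-passing, sorted, rank = index+1
    per_transcript_top_counts: dict[str, int]
    top_n: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    i + 1,
                    r.mirna_id,
                    r.transcript_id,
                    r.site_id,
                    r.mean_rpm_wt,
                    r.mean_rpm_mut,
                    r.enrichment,
                )
                for i, r in enumerate(self.records)
            ],
            columns=[
                "rank", "mirna", "transcript", "site",
                "mean_rpm_wt", "mean_rpm_mut", "enrichment",
            ],
        )


def harmonize_sites(tables: list[HybridTable]) -> list[HybridTable]:
    """Re-key binding sites consistently across samples.

    Sites clustered within each sample independently can differ by a few
    nucleotides of fragment jitter, which would misalign the per-pair keys
    of the enrichment contrast. Overlapping site intervals from all samples
    are merged (single linkage) per transcript and every row is re-keyed to
    its merged site, with counts re-aggregated and RPM recomputed.
    """
    merged: dict[str, list[list[int]]] = defaultdict(list)
    for t in tables:
        for row in t.frame.itertuples():
            ivs = merged[row.transcript]
            ivs.append([row.start, row.end])
    unions: dict[str, list[tuple[int, int]]] = {}
    for tid, ivs in merged.items():
        ivs.sort()
        out = [tuple(ivs[0])]
        for s, e in ivs[1:]:
            ps, pe = out[-1]
            if s < pe:
                out[-1] = (ps, max(pe, e))
            else:
                out.append((s, e))
        unions[tid] = out

    def site_of(tid: str, s: int, e: int) -> tuple[int, int]:
        for us, ue in unions[tid]:
            if s < ue and us < e:
                return us, ue
        return s, e

    out_tables = []
    for t in tables:
        rows: dict[tuple, int] = defaultdict(int)
        for row in t.frame.itertuples():
            us, ue = site_of(row.transcript, row.start, row.end)
            rows[(row.mirna, row.transcript, f"{row.transcript}:{us}-{ue}", us, ue)] += (
                row.count
            )
        frame = pd.DataFrame(
            [
                (t.sample_id, m, tid, sid, s, e, c, c / t.total_hybrids * 1e6)
                for (m, tid, sid, s, e), c in sorted(rows.items())
            ],
            columns=[
                "sample", "mirna", "transcript", "site", "start", "end", "count", "rpm",
            ],
        )
        out_tables.append(
            HybridTable(frame=frame, sample_id=t.sample_id, total_hybrids=t.total_hybrids)
        )
    return out_tables


def _mean_rpm(tables: list[HybridTable]) -> dict[tuple[str, str, str], float]:
    """Mean per-replicate RPM per (mirna, transcript, site); absent rows = 0."""
    sums: dict[tuple[str, str, str], float] = defaultdict(float)
    for t in tables:
        for row in t.frame.itertuples():
            sums[(row.mirna, row.transcript, row.site)] += row.rpm
    return {k: v / len(tables) for k, v in sums.items()}


def compute_enrichment(
    tables_wt: list[HybridTable],
    tables_mut: list[HybridTable],
    pseudocount: float = 0.01,
    rpm_threshold: float = 0.1,
) -> list[EnrichmentRecord]:
    """Per-pair enrichment = (mean_rpm_mut + p) / (mean_rpm_wt + p).

    Pairs are aligned on (mirna, transcript, site) with absent entries as 0;
    ``passes_abundance`` requires max of the two group means above
    ``rpm_threshold`` (the permissive reading of an abundance filter that
    does not name a group).
    """
    if not tables_wt or not tables_mut:
        raise ValueError("both genotype groups need at least one hybrid table")
    wt = _mean_rpm(tables_wt)
    mut = _mean_rpm(tables_mut)
    out = []
    for key in sorted(set(wt) | set(mut)):
        w = wt.get(key, 0.0)
        m = mut.get(key, 0.0)
        out.append(
            EnrichmentRecord(
                mirna_id=key[0],
                transcript_id=key[1],
                site_id=key[2],
                mean_rpm_wt=w,
                mean_rpm_mut=m,
                enrichment=(m + pseudocount) / (w + pseudocount),
                passes_abundance=max(w, m) > rpm_threshold,
                n_wt=len(tables_wt),
                n_mut=len(tables_mut),
            )
        )
    return out


def rank_candidates(records: list[EnrichmentRecord], top_n: int = 25) -> RankedReport:
    """Sort abundance-passing records by enrichment (descending).

    Ties break toward higher mean mutant RPM, then lexicographic ids. The
    report also counts, per transcript, how many of its pairs fall in the
    top ``top_n``.
    """
    kept = [r for r in records if r.passes_abundance]
    kept.sort(
        key=lambda r: (
            -r.enrichment,
            -r.mean_rpm_mut,
            r.mirna_id,
            r.transcript_id,
            r.site_id,
        )
    )
    counts: dict[str, int] = defaultdict(int)
    for r in kept[:top_n]:
        counts[r.transcript_id] += 1
    return RankedReport(records=kept, per_transcript_top_counts=dict(counts), top_n=top_n)


def aggregate_family_sites(
    records: list[EnrichmentRecord],
    family_map: dict[str, str],
    pseudocount: float = 0.01,
    coverage_min: float = 0.5,
) -> list[TriggerCandidate]:
    """Aggregate per-pair records into per-(site, family) trigger candidates.

    member_coverage = members of the family observed in >= 1 hybrid at the
    site / family size; aggregate_enrichment is the pseudocounted ratio of
    the summed member mean RPMs. Candidates with coverage below
    ``coverage_min`` are excluded; the rest are ranked by aggregate
    enrichment (ties toward higher summed mutant RPM, then ids).
    """
    unknown = {r.mirna_id for r in records} - set(family_map)
    if unknown:
        raise KeyError(f"miRNA(s) missing from family map: {sorted(unknown)}")
    fam_sizes: dict[str, int] = defaultdict(int)
    for fam in family_map.values():
        fam_sizes[fam] += 1
    groups: dict[tuple[str, str, str], list[EnrichmentRecord]] = defaultdict(list)
    for r in records:
        groups[(r.transcript_id, r.site_id, family_map[r.mirna_id])].append(r)
    cands = []
    for (tid, sid, fam), rs in groups.items():
        observed = {r.mirna_id for r in rs if r.mean_rpm_wt + r.mean_rpm_mut > 0}
        coverage = len(observed) / fam_sizes[fam]
        sum_wt = sum(r.mean_rpm_wt for r in rs)
        sum_mut = sum(r.mean_rpm_mut for r in rs)
        agg = (sum_mut + pseudocount) / (sum_wt + pseudocount)
        cands.append((agg, sum_mut, tid, sid, fam, coverage))
    cands = [c for c in cands if c[5] >= coverage_min]
    cands.sort(key=lambda c: (-c[0], -c[1], c[2], c[3], c[4]))
    return [
        TriggerCandidate(
            transcript_id=tid,
            site_id=sid,
            family_id=fam,
            member_coverage=coverage,
            aggregate_enrichment=agg,
            rank=i + 1,
        )
        for i, (agg, _, tid, sid, fam, coverage) in enumerate(cands)
    ]
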