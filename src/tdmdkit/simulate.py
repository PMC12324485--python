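"""Synthetic study generator with planted ground truth.

Emulates the data shapes of a TDMD-trigger discovery study in an early
embryo / L1 system: an 8-member miRNA seed family, a trigger lncRNA carrying
two binding sites (a perfect-seed site and an offset g3-g8 site with
extensive 3' pairing to one designated member), chimeric-eCLIP hybrid
libraries in wild-type vs decay-deficient genotypes, stage/genotype small-RNA
count tables with guide-specific stabilization, isomiR read sets with
genotype-dependent 3' trimming, and qPCR / smFISH quantification fixtures.

Every generator is deterministic given ``SimConfig.rng_seed`` (independent
derived streams per operation), and every planted quantity is recorded in
:class:`SimTruth` so downstream estimators can be tested for parameter
recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import revcomp_rna, to_dna, to_rna
from .decay import CountTable
from .duplex import predict_duplex
from .mirna import MiRNARecord, guides

GENOTYPES = ("wild_type", "decay_null")
STAGES = ("embryo", "L1")

#: Untemplated tail nucleotide distribution (uridylation-dominated).
TAIL_NT_DIST = {"U": 0.70, "A": 0.20, "G": 0.05, "C": 0.05}

_GT_CODE = {"wild_type": 0, "decay_null": 1}
_STAGE_CODE = {"embryo": 0, "L1": 1}


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic study. See docs/methods.md."""

    rng_seed: int = 0
    # family / transcriptome
    family_size: int = 8
    mirna_length: int = 22
    n_decoy_transcripts: int = 30
    decoy_seed_site_fraction: float = 0.5
    trigger_length: int = 882
    decoy_length: int = 600
    trigger_site1_3p_pairing: tuple[int, ...] | None = None  # per member
    trigger_site2_member: int = 3
    trigger_site2_3p_pairing: int = 14
    trigger_expression: float = 1.0
    # chimeric libraries
    enrichment_lambda: float = 4.0
    hybrid_depth: int = 200_000
    background_fraction: float = 0.10
    pcr_duplication_mean: float = 1.0
    umi_len: int = 4
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    # count tables
    decay_fold: float | tuple[float, ...] = 7.1
    etol1_decay: float = 10.0
    n_replicates: int = 4
    srna_depth: int = 1_000_000
    nb_dispersion: float = 0.05
    n_pirna: int = 50
    n_spikein: int = 5
    passenger_fraction: float = 0.02
    # isomiRs
    trim_prob: float = 0.05
    tail_prob: float = 0.05
    trim_tail_prob: float = 0.0
    elevated_trim_prob: float = 0.20
    trim_elevated_genotype: str = "decay_null"
    tdtt_min_planted_3p: int = 8  # members with >= this 3' pairing get TDTT
    isoform_depth: int = 10_000
    tail_nt_dist: dict = field(default_factory=lambda: dict(TAIL_NT_DIST))
    # qPCR / absolute quantification
    qpcr_efficiency: float = 0.95
    qpcr_ct_sd: float = 0.10
    qpcr_intercept: float = 38.0
    qpcr_input_ng: float = 10.0
    true_trigger_l1_copies_per_ng: float = 89_836.0
    true_ref_mirna_copies_per_ng: float = 192_252.0
    true_peak_copies_per_ng: tuple[float, float] = (398_941.0, 346_742.0)
    stage_weights: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.2, 0.3, 0.5),
        (0.4, 0.3, 0.3),
    )
    stage_profile: tuple[float, ...] = (0.1, 0.6, 1.0)  # relative to peak
    # smFISH
    spot_unit_intensity: float = 1000.0
    spot_intensity_cv: float = 0.2
    n_embryos_per_stage: int = 50
    spot_stage_mean_spots: dict = field(
        default_factory=lambda: {"bean": 5.0, "pretzel": 117.5}
    )
    spot_stage_k_mixture: dict = field(
        default_factory=lambda: {
            "bean": {1: 1.0},
            "pretzel": {1: 0.60, 2: 0.25, 3: 0.10, 4: 0.05},
        }
    )

    def __post_init__(self) -> None:
        if self.family_size < 2:
            raise InvalidConfigError("family_size must be >= 2")
        if self.mirna_length < 18:
            raise InvalidConfigError("mirna_length must be >= 18")
        if self.enrichment_lambda < 1:
            raise InvalidConfigError("enrichment_lambda must be >= 1")
        if self.hybrid_depth <= 0 or self.srna_depth <= 0:
            raise InvalidConfigError("library depths must be positive")
        for fc in np.atleast_1d(np.asarray(self.decay_fold, dtype=float)):
            if fc < 1:
                raise InvalidConfigError("decay_fold must be >= 1 per member")
        probs = (
            self.trim_prob,
            self.tail_prob,
            self.trim_tail_prob,
            self.elevated_trim_prob,
            self.background_fraction,
            self.decoy_seed_site_fraction,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise InvalidConfigError("probabilities must lie in [0, 1]")
        if self.trim_prob + self.tail_prob + self.trim_tail_prob > 1:
            raise InvalidConfigError("trim_prob + tail_prob (+ both) exceed 1")
        if self.elevated_trim_prob + self.tail_prob + self.trim_tail_prob > 1:
            raise InvalidConfigError("elevated trim + tail probabilities exceed 1")
        if not 0 < self.qpcr_efficiency <= 1.2:
            raise InvalidConfigError("qpcr_efficiency must lie in (0, 1.2]")
        if self.trigger_site1_3p_pairing is None:
            pairing = [2] * self.family_size
            pairing[0] = 12
            if self.family_size > 2:
                pairing[2] = 11
            self.trigger_site1_3p_pairing = tuple(pairing)
        if len(self.trigger_site1_3p_pairing) != self.family_size:
            raise InvalidConfigError("trigger_site1_3p_pairing must cover every member")
        if not 0 <= self.trigger_site2_member < self.family_size:
            raise InvalidConfigError("trigger_site2_member out of range")

    def member_decay_folds(self) -> tuple[float, ...]:
        if np.isscalar(self.decay_fold):
            return tuple([float(self.decay_fold)] * self.family_size)
        if len(self.decay_fold) != self.family_size:
            raise InvalidConfigError("decay_fold must be scalar or one per member")
        return tuple(float(f) for f in self.decay_fold)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimTruth:
    """Planted ground truth of one synthetic study."""

    trigger_transcript_id: str
    site1_span: tuple[int, int]
    site2_span: tuple[int, int]
    site1_guide_id: str  # guide whose seed complement is planted at site 1
    site2_member_id: str
    member_ids: tuple[str, ...]
    passenger_ids: tuple[str, ...]
    decay_folds: dict[str, float]
    tdtt_member_ids: tuple[str, ...]
    decoy_sites: tuple[tuple[str, tuple[int, int]], ...]
    isoform_probs: dict[str, dict[str, dict[str, float]]]  # genotype->member->probs
    transcript_expression: dict[str, float] = field(default_factory=dict)
    quant: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for span in (self.site1_span, self.site2_span):
            if span[0] >= span[1]:
                raise ValueError("site spans must be non-empty half-open intervals")
        if not (
            self.site1_span[1] <= self.site2_span[0]
            or self.site2_span[1] <= self.site1_span[0]
        ):
            raise ValueError("trigger sites must not overlap")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.rng_seed)] + [int(s) for s in stream])


def _rand_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# miRNA family


def make_mirna_family(config: SimConfig) -> list[MiRNARecord]:
    """Generate guide+passenger records for one seed family.

    All guides share positions 2-8 (the family seed) and a 5'U; 3' regions
    (positions 9..end) are redrawn until every pair of members differs at
    >= 30% of positions. Passenger strands follow the generator's hairpin
    rule: reverse complement of the guide from position 3 onward plus two
    random 3' nucleotides (mimicking the 2-nt 3' overhang of a miRNA
    duplex). Each guide carries 15 nt of downstream genomic context.
    """
    rng = _rng(config, 1)
    seed7 = _rand_rna(rng, 7)
    tail_len = config.mirna_length - 8
    pairing = config.trigger_site1_3p_pairing
    # draw well past the 30% minimum divergence so one member's 3' end does
    # not pair appreciably with another member's planted complement block
    min_diff = int(np.ceil(0.55 * tail_len))

    # High-3'-pairing members are drawn first; their 3' termini define the
    # trigger's site-1 complement blocks. Low-pairing members are then
    # rejection-sampled so their chance 3' pairing against those blocks
    # stays below the TDTT-extent threshold and the seed register holds --
    # otherwise chance complementarity (incl. G:U wobble) would contradict
    # the planted per-member pairing truth. Moderate residual pairing
    # (extent <= 6) is accepted: real sites show variable background pairing.
    order = sorted(range(config.family_size), key=lambda m: -pairing[m])
    tails: dict[int, str] = {}

    def site1_core() -> str:
        blocks = sorted(
            (pairing[m], revcomp_rna(("U" + seed7 + tails[m])[-pairing[m]:]))
            for m in tails
            if pairing[m] >= 4
        )
        return "".join(b for _, b in blocks) + revcomp_rna(seed7)

    for m in order:
        fallback: tuple[int, str] | None = None
        for _ in range(300):
            cand = _rand_rna(rng, tail_len)
            if any(
                sum(a != b for a, b in zip(cand, t)) < min_diff for t in tails.values()
            ):
                continue
            if pairing[m] < 4 and any(pairing[h] >= 4 for h in tails):
                guide = "U" + seed7 + cand
                d = predict_duplex(guide, site1_core())
                paired = d.paired_g
                if not all(g in paired for g in range(2, 9)):
                    continue
                ext = sum(g in paired for g in range(9, len(guide) + 1))
                if fallback is None or ext < fallback[0]:
                    fallback = (ext, cand)
                if ext > 4:
                    continue
            tails[m] = cand
            break
        else:  # best-effort: keep the lowest-extent candidate seen
            if fallback is None:
                raise InvalidConfigError("could not draw a divergent miRNA family")
            tails[m] = fallback[1]

    records: list[MiRNARecord] = []
    for m in range(config.family_size):
        tail = tails[m]
        gid = f"mirf-{m + 1:02d}"
        seq = "U" + seed7 + tail
        context = _rand_rna(rng, 15)
        records.append(
            MiRNARecord(gid, seq, "guide", "mir35fam", downstream_context=context)
        )
        passenger = revcomp_rna(seq[2:]) + _rand_rna(rng, 2)
        records.append(MiRNARecord(gid + "*", passenger, "passenger", "mir35fam"))
    return records


def make_outsider_mirna(config: SimConfig, family: list[MiRNARecord]) -> MiRNARecord:
    """A ninth, non-family guide miRNA whose seed differs from the family's."""
    rng = _rng(config, 9)
    fam_seed = guides(family)[0].seed
    while True:
        seq = "U" + _rand_rna(rng, config.mirna_length - 1)
        if sum(a != b for a, b in zip(seq[1:8], fam_seed)) >= 4:
            break
    return MiRNARecord(
        "mirx-01", seq, "guide", "mirxfam", downstream_context=_rand_rna(rng, 15)
    )


# ---------------------------------------------------------------------------
# transcriptome


def _site1_sequence(
    config: SimConfig, fam_guides: list[MiRNARecord], site1_guide: MiRNARecord
) -> str:
    """Site-1 target sequence, 5'->3' (DNA).

    Layout: [3'-complement blocks, farthest member first] [seed complement of
    g2-g8] [non-pairing nt opposite g1]. Members with planted 3' pairing
    below 4 nt get no engineered block; each engineered block is the reverse
    complement of that member's 3' terminus, placed at a member-specific
    offset so members keep divergent 3' sequences (the duplex then shows a
    target-side bulge between seed and 3' pairing, as in real site diagrams).
    """
    blocks = []
    for m, c in enumerate(config.trigger_site1_3p_pairing):
        if c >= 4:
            blocks.append((c, revcomp_rna(fam_guides[m].sequence[-c:])))
    blocks.sort()  # ascending planted count: largest block ends up seed-adjacent
    seedcomp = revcomp_rna(site1_guide.sequence[1:8])
    anti_g1 = site1_guide.sequence[0]  # identical base never pairs (no WC/GU)
    return to_dna("".join(b for _, b in blocks) + seedcomp + anti_g1)


def _site2_sequence(config: SimConfig, fam_guides: list[MiRNARecord]) -> str:
    """Site-2 target sequence: g3-g8 complement only, extensive 3' pairing
    to the designated member, and a deliberate mismatch opposite g2."""
    member = fam_guides[config.trigger_site2_member]
    block = revcomp_rna(member.sequence[-config.trigger_site2_3p_pairing:])
    comp3_8 = revcomp_rna(member.sequence[2:8])
    # a same-base run opposite g2 pairs neither WC nor G:U; three copies keep
    # any pairable downstream base out of reach at positive score
    anti_g2 = member.sequence[1] * 3
    return to_dna(block + comp3_8 + anti_g2)


def make_transcriptome(
    config: SimConfig,
    family: list[MiRNARecord],
    site1_guide: MiRNARecord | None = None,
) -> tuple[dict[str, str], SimTruth]:
    """Trigger lncRNA + decoy transcripts (DNA, sense strand) with truth.

    ``site1_guide`` overrides which guide's seed complement is planted at
    site 1 (default: the family seed shared by all members); passing a
    non-family miRNA emulates seed-retargeting of the trigger.
    """
    rng = _rng(config, 2)
    fam_guides = guides(family)
    if site1_guide is None:
        site1_guide = fam_guides[0]
    trig_id = "lnc-trig-1"

    seq = list(_rand_dna(rng, config.trigger_length))
    s1 = _site1_sequence(config, fam_guides, site1_guide)
    s2 = _site2_sequence(config, fam_guides)
    pos1 = config.trigger_length // 3
    pos2 = 2 * config.trigger_length // 3
    if pos1 + len(s1) > pos2 or pos2 + len(s2) > config.trigger_length:
        raise InvalidConfigError("trigger_length too short for planted sites")
    seq[pos1 : pos1 + len(s1)] = s1
    seq[pos2 : pos2 + len(s2)] = s2

    # Clustered binding-site spans overshoot the planted span by a few nt
    # of fragment jitter, so classification windows see a little flanking
    # sequence; redraw the flanks until every member's optimal duplex in a
    # jitter-margin window matches its planted architecture (seed register
    # held; 3' pairing extensive only for members with a planted complement
    # block). Chance flank complementarity would otherwise contradict the
    # recorded truth.
    retarget_check = site1_guide.id in {g.id for g in fam_guides}
    # random flank draws first; deterministic homopolymer flanks as a last
    # resort (homopolymers support only isolated pairs, which score < 0)
    flank_plan = [(_rand_dna(rng, 10), _rand_dna(rng, 10)) for _ in range(80)]
    flank_plan += [(a * 10, b * 10) for a in "ACGT" for b in "ACGT"]
    for flank5, flank3 in flank_plan:
        seq[pos1 - 10 : pos1] = flank5
        seq[pos1 + len(s1) : pos1 + len(s1) + 10] = flank3
        if not retarget_check:
            break
        window = to_rna("".join(seq[pos1 - 3 : pos1 + len(s1) + 3]))
        ok = True
        for g, planted in zip(fam_guides, config.trigger_site1_3p_pairing):
            d = predict_duplex(g.sequence, window)
            paired = d.paired_g
            if not all(k in paired for k in range(2, 9)):
                ok = False
                break
            L = len(g.sequence)
            extent = sum(k in paired for k in range(9, L + 1))
            last3 = sum(k in paired for k in range(L - 2, L + 1))
            if planted < 4 and extent > 7:  # must stay below the TDTT rule
                ok = False
                break
            if planted >= config.tdtt_min_planted_3p and not (
                extent >= 8 and last3 >= 2
            ):
                ok = False
                break
        if ok:
            break

    # Same treatment for the flanks around site 2: the designated member
    # must keep the offset (g3-g8) register with g2 unpaired and extensive
    # 3' pairing.
    site2_member = fam_guides[config.trigger_site2_member]
    flank_plan2 = [(_rand_dna(rng, 10), _rand_dna(rng, 10)) for _ in range(80)]
    flank_plan2 += [(a * 10, b * 10) for a in "ACGT" for b in "ACGT"]
    for flank5, flank3 in flank_plan2:
        window = to_rna("".join(seq[pos2 - 3 : pos2 + len(s2) + 3]))
        d = predict_duplex(site2_member.sequence, window)
        paired = d.paired_g
        L = len(site2_member.sequence)
        if (
            2 not in paired
            and all(k in paired for k in range(3, 9))
            and sum(k in paired for k in range(9, L + 1)) >= 8
        ):
            break
        seq[pos2 - 10 : pos2] = flank5
        seq[pos2 + len(s2) : pos2 + len(s2) + 10] = flank3
    transcripts = {trig_id: "".join(seq)}

    seed_site = to_dna(revcomp_rna(fam_guides[0].sequence[1:8]))
    decoy_sites = []
    expression = {trig_id: config.trigger_expression}
    for d in range(config.n_decoy_transcripts):
        tid = f"decoy-{d + 1:03d}"
        dseq = list(_rand_dna(rng, config.decoy_length))
        if rng.random() < config.decoy_seed_site_fraction:
            p = int(rng.integers(50, config.decoy_length - 50))
            dseq[p : p + len(seed_site)] = seed_site
            decoy_sites.append((tid, (p, p + len(seed_site))))
        transcripts[tid] = "".join(dseq)
        # conventional targets (mRNAs) are collectively far more abundant
        # than the trigger lncRNA, so trigger hybrids stay a small fraction
        expression[tid] = float(np.exp(rng.uniform(np.log(1.0), np.log(10.0))))

    folds = config.member_decay_folds()
    retargeted = site1_guide.id not in {g.id for g in fam_guides}
    decay_folds = {}
    for g, f in zip(fam_guides, folds):
        # Retargeting site 1 removes family decay except for the site-2
        # member, which keeps mild redundant decay through site 2.
        if retargeted:
            decay_folds[g.id] = (
                min(f, 2.0) if g.id == fam_guides[config.trigger_site2_member].id else 1.0
            )
        else:
            decay_folds[g.id] = f
    if retargeted:
        decay_folds[site1_guide.id] = float(np.max(folds))

    tdtt_ids = tuple(
        fam_guides[m].id
        for m, c in enumerate(config.trigger_site1_3p_pairing)
        if c >= config.tdtt_min_planted_3p
    )
    iso = {}
    for gt in GENOTYPES:
        iso[gt] = {}
        for g in fam_guides:
            trim = config.trim_prob
            if g.id in tdtt_ids and gt == config.trim_elevated_genotype and not retargeted:
                trim = config.elevated_trim_prob
            iso[gt][g.id] = {
                "trim": trim,
                "tail": config.tail_prob,
                "trim_tail": config.trim_tail_prob,
            }

    peak_a, peak_b = config.true_peak_copies_per_ng
    quant = {
        "trigger_l1_copies_per_ng": config.true_trigger_l1_copies_per_ng,
        "ref_mirna_l1_copies_per_ng": config.true_ref_mirna_copies_per_ng,
        "peak_copies_per_ng": {"embryo_mix_a": peak_a, "embryo_mix_b": peak_b},
        "stage_weights": {
            "embryo_mix_a": list(config.stage_weights[0]),
            "embryo_mix_b": list(config.stage_weights[1]),
        },
        "stage_profile": list(config.stage_profile),
        "smfish_mean_molecules": {
            stage: config.spot_stage_mean_spots[stage]
            * sum(k * w for k, w in config.spot_stage_k_mixture[stage].items())
            for stage in config.spot_stage_mean_spots
        },
    }

    truth = SimTruth(
        trigger_transcript_id=trig_id,
        site1_span=(pos1, pos1 + len(s1)),
        site2_span=(pos2, pos2 + len(s2)),
        site1_guide_id=site1_guide.id,
        site2_member_id=fam_guides[config.trigger_site2_member].id,
        member_ids=tuple(g.id for g in fam_guides),
        passenger_ids=tuple(r.id for r in family if r.role == "passenger"),
        decay_folds=decay_folds,
        tdtt_member_ids=tdtt_ids,
        decoy_sites=tuple(decoy_sites),
        isoform_probs=iso,
        transcript_expression=expression,
        quant=quant,
    )
    return transcripts, truth


# ---------------------------------------------------------------------------
# chimeric eCLIP libraries


@dataclass(frozen=True)
class Interaction:
    mirna_id: str
    transcript_id: str
    span: tuple[int, int]
    weight: float


def interaction_table(
    mirnas: list[MiRNARecord],
    transcripts: dict[str, str],
    truth: SimTruth,
    flank: int = 5,
) -> list[Interaction]:
    """Guide x planted-site interaction weights.

    The sampling weight is the duplex score (floored at 0; non-pairing
    combinations are dropped) scaled by the target transcript's expression
    level, so hybrid capture reflects both pairing strength and target
    abundance.
    """
    sites = [
        (truth.trigger_transcript_id, truth.site1_span),
        (truth.trigger_transcript_id, truth.site2_span),
        *truth.decoy_sites,
    ]
    out = []
    for g in guides(mirnas):
        for tid, (s, e) in sites:
            seq = transcripts[tid]
            window = to_rna(seq[max(0, s - flank) : min(len(seq), e + flank)])
            score = predict_duplex(g.sequence, window).score
            expr = truth.transcript_expression.get(tid, 1.0)
            if score > 0:
                out.append(Interaction(g.id, tid, (s, e), float(score) * expr))
    return out


def simulate_hybrid_counts(
    config: SimConfig,
    interactions: list[Interaction],
    truth: SimTruth,
    genotype: str,
    rng: np.random.Generator,
    depth: int | None = None,
) -> tuple[dict[Interaction, int], int]:
    """Multinomial unique-molecule counts per interaction plus background.

    Sampling weights are proportional to duplex score scaled by target
    expression. In the decay-deficient genotype, trigger-transcript
    interactions are stabilized (the complexes that would have been
    degraded accumulate): the multiplier interpolates from 1 up to
    ``enrichment_lambda`` with the planted decay fold of the miRNA, so an
    interaction that drives no decay gains no enrichment. Returns (counts
    by interaction, number of background molecules).
    """
    if genotype not in GENOTYPES:
        raise InvalidConfigError(f"unknown genotype {genotype!r}")
    depth = config.hybrid_depth if depth is None else depth
    if depth <= 0:
        raise InvalidConfigError("hybrid depth must be positive")
    w = np.array([it.weight for it in interactions], dtype=float)
    if genotype == "decay_null":
        max_fold = max(truth.decay_folds.values(), default=1.0)
        lam = config.enrichment_lambda
        mult = np.ones(len(interactions))
        if max_fold > 1:
            for k, it in enumerate(interactions):
                if it.transcript_id == truth.trigger_transcript_id:
                    fold = truth.decay_folds.get(it.mirna_id, 1.0)
                    mult[k] = 1 + (lam - 1) * max(0.0, fold - 1) / (max_fold - 1)
        w = w * mult
    bg = config.background_fraction / (1 - config.background_fraction) * w.sum()
    probs = np.append(w, bg)
    probs /= probs.sum()
    draws = rng.multinomial(depth, probs)
    counts = {it: int(c) for it, c in zip(interactions, draws[:-1]) if c > 0}
    return counts, int(draws[-1])


@dataclass
class SimulatedLibrary:
    """Rendered chimeric library: reads plus per-insert truth labels."""

    reads: list[tuple[str, str]]  # (read_id, sequence) after PCR duplication
    n_unique_molecules: int
    truth_labels: dict[str, tuple[str, str, int] | None]  # insert truth by read seq


def simulate_chimeric_reads(
    config: SimConfig,
    mirnas: list[MiRNARecord],
    transcripts: dict[str, str],
    truth: SimTruth,
    genotype: str,
    interactions: list[Interaction] | None = None,
    depth: int | None = None,
    fastq_path: str | Path | None = None,
) -> SimulatedLibrary:
    """Render one chimeric eCLIP library as reads (optionally gzip FASTQ).

    Read architecture: UMI(4) + [miRNA arm and target fragment in random
    order] + UMI(4) + 3' adapter. Each unique molecule is emitted
    1 + Poisson(pcr_duplication_mean) times; background molecules are
    target-only fragments.
    """
    rng = _rng(config, 10, _GT_CODE[genotype])
    if interactions is None:
        interactions = interaction_table(mirnas, transcripts, truth)
    counts, n_bg = simulate_hybrid_counts(
        config, interactions, truth, genotype, rng, depth=depth
    )
    tids = list(transcripts)
    molecules: list[tuple[str, tuple | None]] = []
    for it, c in counts.items():
        tseq = transcripts[it.transcript_id]
        arm = to_dna(next(m.sequence for m in mirnas if m.id == it.mirna_id))
        for _ in range(c):
            # crosslink fragment: site span + <=2 nt jitter per side, padded
            # to >= 24 nt so short seed-only sites still yield mappable arms
            jl, jr = int(rng.integers(0, 3)), int(rng.integers(0, 3))
            L = it.span[1] - it.span[0]
            deficit = max(0, 24 - (L + jl + jr))
            dl = int(rng.integers(0, deficit + 1))
            s = max(0, it.span[0] - jl - dl)
            e = min(len(tseq), it.span[1] + jr + (deficit - dl))
            frag = tseq[s:e]
            insert = arm + frag if rng.random() < 0.5 else frag + arm
            molecules.append((insert, (it.mirna_id, it.transcript_id, s)))
    for _ in range(n_bg):
        tid = tids[int(rng.integers(len(tids)))]
        tseq = transcripts[tid]
        ln = int(rng.integers(25, 41))
        s = int(rng.integers(0, max(1, len(tseq) - ln)))
        molecules.append((tseq[s : s + ln], None))

    reads: list[tuple[str, str]] = []
    labels: dict[str, tuple | None] = {}
    for i, (insert, label) in enumerate(molecules):
        umi5 = _rand_dna(rng, config.umi_len)
        umi3 = _rand_dna(rng, config.umi_len)
        seq = umi5 + insert + umi3 + config.adapter3
        labels[seq] = label
        copies = 1 + int(rng.poisson(config.pcr_duplication_mean))
        for c in range(copies):
            reads.append((f"sim:{i}:{c}", seq))
    rng.shuffle(reads)

    if fastq_path is not None:
        import gzip

        with gzip.open(fastq_path, "wt") as fh:
            for rid, seq in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return SimulatedLibrary(
        reads=reads, n_unique_molecules=len(molecules), truth_labels=labels
    )


def tabulate_simulated_hybrids(
    counts: dict[Interaction, int], sample_id: str
) -> "HybridTable":
    """HybridTable straight from interaction counts (no read rendering).

    Site ids come from the planted spans; RPM is normalized to total hybrid
    molecules exactly as :func:`tdmdkit.chimera.tabulate_hybrids` does for
    called reads.
    """
    from .chimera import HybridTable

    total = sum(counts.values())
    if total == 0:
        raise ValueError("no hybrid molecules to tabulate")
    rows = [
        (
            sample_id,
            it.mirna_id,
            it.transcript_id,
            f"{it.transcript_id}:{it.span[0]}-{it.span[1]}",
            it.span[0],
            it.span[1],
            c,
            c / total * 1e6,
        )
        for it, c in sorted(counts.items(), key=lambda kv: (kv[0].mirna_id, kv[0].transcript_id, kv[0].span))
    ]
    frame = pd.DataFrame(
        rows,
        columns=["sample", "mirna", "transcript", "site", "start", "end", "count", "rpm"],
    )
    return HybridTable(frame=frame, sample_id=sample_id, total_hybrids=total)


def simulate_hybrid_study(
    config: SimConfig,
    mirnas: list[MiRNARecord],
    transcripts: dict[str, str],
    truth: SimTruth,
    interactions: list[Interaction] | None = None,
) -> dict[str, list["HybridTable"]]:
    """n_replicates hybrid tables per genotype, at count level."""
    if interactions is None:
        interactions = interaction_table(mirnas, transcripts, truth)
    out: dict[str, list] = {}
    for gt in GENOTYPES:
        rng = _rng(config, 10, _GT_CODE[gt])
        tables = []
        for r in range(config.n_replicates):
            counts, _ = simulate_hybrid_counts(config, interactions, truth, gt, rng)
            tables.append(tabulate_simulated_hybrids(counts, f"{gt}_r{r + 1}"))
        out[gt] = tables
    return out


# ---------------------------------------------------------------------------
# count tables


def _member_base_abundance(config: SimConfig) -> np.ndarray:
    rng = _rng(config, 17)
    return np.exp(rng.uniform(np.log(2e3), np.log(2e4), size=config.family_size))


def simulate_count_tables(
    config: SimConfig,
    truth: SimTruth,
    genotype: str,
    stage: str,
    extra_guides: dict[str, float] | None = None,
) -> CountTable:
    """Negative-binomial count table for n_replicates libraries.

    Guide-strand means are divided by ``etol1_decay`` at L1 and multiplied by
    the planted per-member fold in the decay-deficient genotype; passenger,
    piRNA and spike-in means are genotype-independent. ``extra_guides`` adds
    guide features (id -> relative embryo abundance) outside the family,
    stabilized per ``truth.decay_folds`` if present there.
    """
    if genotype not in GENOTYPES or stage not in STAGES:
        raise InvalidConfigError(f"unknown genotype/stage {genotype}/{stage}")
    base = _member_base_abundance(config)
    rng = _rng(config, 20, _GT_CODE[genotype], _STAGE_CODE[stage])
    feats: list[str] = []
    classes: list[str] = []
    means: list[float] = []

    def guide_mean(gid: str, embryo_level: float) -> float:
        if stage == "embryo":
            return embryo_level
        mu = embryo_level / config.etol1_decay
        if genotype == "decay_null":
            mu *= truth.decay_folds.get(gid, 1.0)
        return mu

    for gid, b in zip(truth.member_ids, base):
        feats.append(gid)
        classes.append("mirna_guide")
        means.append(guide_mean(gid, b))
    for (gid, b) in (extra_guides or {}).items():
        feats.append(gid)
        classes.append("mirna_guide")
        means.append(guide_mean(gid, b))
    for pid, b in zip(truth.passenger_ids, base):
        feats.append(pid)
        classes.append("mirna_passenger")
        means.append(b * config.passenger_fraction)
    pirna_means = np.exp(
        _rng(config, 18).uniform(np.log(50), np.log(2000), size=config.n_pirna)
    )
    for j, mu in enumerate(pirna_means):
        feats.append(f"pirna-{j + 1:03d}")
        classes.append("pirna")
        means.append(mu)
    for j in range(config.n_spikein):
        feats.append(f"spike-{j + 1:02d}")
        classes.append("spikein")
        means.append(1000.0)

    mu = np.asarray(means)
    mu = mu / mu.sum() * config.srna_depth
    alpha = config.nb_dispersion
    data = {}
    meta = []
    for r in range(config.n_replicates):
        sid = f"{genotype}_{stage}_r{r + 1}"
        lam = rng.gamma(shape=1 / alpha, scale=mu * alpha) if alpha > 0 else mu
        data[sid] = rng.poisson(lam)
        meta.append((sid, genotype, stage, r + 1))
    counts = pd.DataFrame(data, index=feats)
    samples = pd.DataFrame(
        meta, columns=["sample", "genotype", "stage", "replicate"]
    ).set_index("sample")
    return CountTable(counts, pd.Series(classes, index=feats), samples)


def simulate_experiment(
    config: SimConfig,
    truth: SimTruth,
    genotypes: tuple[str, ...] = GENOTYPES,
    stages: tuple[str, ...] = STAGES,
    extra_guides: dict[str, float] | None = None,
) -> CountTable:
    """One CountTable covering every genotype x stage combination."""
    table: CountTable | None = None
    for gt in genotypes:
        for st in stages:
            t = simulate_count_tables(config, truth, gt, st, extra_guides=extra_guides)
            table = t if table is None else table.concat(t)
    return table


# ---------------------------------------------------------------------------
# isomiR reads


def simulate_isoform_reads(
    config: SimConfig,
    mirnas: list[MiRNARecord],
    truth: SimTruth,
    genotype: str,
    n_reads: int | None = None,
) -> dict[str, list[str]]:
    """Per-guide isomiR read multisets (RNA strings).

    Each read is canonical, 3'-trimmed by 1-3 nt, 3'-tailed with 1-3
    untemplated nt from :data:`TAIL_NT_DIST`, or both, with the
    genotype/member probabilities recorded in ``truth.isoform_probs``.
    """
    rng = _rng(config, 30, _GT_CODE[genotype])
    n = config.isoform_depth if n_reads is None else n_reads
    nts = list(config.tail_nt_dist)
    ps = np.array(list(config.tail_nt_dist.values()))
    ps = ps / ps.sum()
    out: dict[str, list[str]] = {}
    for g in guides(mirnas):
        probs = truth.isoform_probs[genotype].get(g.id)
        if probs is None:
            probs = {"trim": config.trim_prob, "tail": config.tail_prob,
                     "trim_tail": config.trim_tail_prob}
        p_can = 1 - probs["trim"] - probs["tail"] - probs["trim_tail"]
        cls = rng.choice(
            4, size=n, p=[p_can, probs["trim"], probs["tail"], probs["trim_tail"]]
        )
        reads = []
        for c in cls:
            seq = g.sequence
            if c in (1, 3):  # trimmed
                seq = seq[: len(seq) - int(rng.integers(1, 4))]
            if c in (2, 3):  # tailed
                seq = seq + "".join(rng.choice(nts, size=int(rng.integers(1, 4)), p=ps))
            reads.append(seq)
        out[g.id] = reads
    return out


# ---------------------------------------------------------------------------
# qPCR and smFISH fixtures


def ct_model_slope(efficiency: float) -> float:
    """Standard-curve slope (Ct per log10 copies) for a given efficiency."""
    return -1.0 / np.log10(1.0 + efficiency)


def simulate_quant_data(
    config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR table (standards + samples) and smFISH spot-intensity table.

    Ct = intercept + slope * log10(copies/reaction) + N(0, ct_sd), slope
    from the configured amplification efficiency; the standard series spans
    10^2..10^7 copies. Spot intensities are Normal(k*unit, cv*k*unit) for
    planted per-stage molecule-count mixtures over k.
    """
    rng = _rng(config, 40)
    slope = ct_model_slope(config.qpcr_efficiency)
    rows = []

    def ct_of(copies: float) -> float:
        return float(
            config.qpcr_intercept
            + slope * np.log10(copies)
            + rng.normal(0, config.qpcr_ct_sd)
        )

    for species in ("trigger", "mir_ref"):
        for copies in 10.0 ** np.arange(2, 8):
            for _ in range(3):  # standards in technical triplicate
                rows.append((species, "standard", f"{species}_std", copies,
                             ct_of(copies), np.nan))
    q = truth.quant
    samples = {
        ("trigger", "trigger_L1"): q["trigger_l1_copies_per_ng"],
        ("mir_ref", "mir_ref_L1"): q["ref_mirna_l1_copies_per_ng"],
    }
    profile = np.array(q["stage_profile"])
    for mix, peak in q["peak_copies_per_ng"].items():
        w = np.array(q["stage_weights"][mix])
        samples[("trigger", f"trigger_{mix}")] = peak * float(w @ profile)
    for (species, sid), per_ng in samples.items():
        for _ in range(3):
            copies = per_ng * config.qpcr_input_ng
            rows.append((species, "sample", sid, np.nan, ct_of(copies),
                         config.qpcr_input_ng))
    qpcr = pd.DataFrame(
        rows, columns=["species", "role", "sample_id", "copies", "ct", "input_ng"]
    )

    spot_rows = []
    for stage, mean_spots in config.spot_stage_mean_spots.items():
        mix = config.spot_stage_k_mixture[stage]
        ks = np.array(list(mix))
        ws = np.array(list(mix.values()), dtype=float)
        ws /= ws.sum()
        for e in range(config.n_embryos_per_stage):
            eid = f"{stage}_{e + 1:03d}"
            n_spots = int(rng.poisson(mean_spots))
            kdraw = rng.choice(ks, size=n_spots, p=ws)
            for s, k in enumerate(kdraw):
                inten = rng.normal(
                    k * config.spot_unit_intensity,
                    config.spot_intensity_cv * k * config.spot_unit_intensity,
                )
                spot_rows.append((eid, stage, s + 1, max(float(inten), 1e-9)))
    spots = pd.DataFrame(
        spot_rows, columns=["embryo_id", "stage", "spot_id", "integrated_intensity"]
    )
    return qpcr, spots
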