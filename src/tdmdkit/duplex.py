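"""Intermolecular miRNA:target duplex prediction and pairing-architecture calls.

The duplex predictor is a score-based dynamic program over non-crossing base
pair sets, global on the miRNA and local on the target window. It reports
pairing *topology* (which miRNA positions pair, and where on the trigger),
which is what the downstream architecture classification consumes; it does not
estimate folding free energies.

Scoring of a candidate pair set: each pair contributes +2 (Watson-Crick) or
+0.5 (G:U wobble). Internal unpaired stretches between consecutive pairs, with ``a``
miRNA and ``b`` target nucleotides, cost ``mismatch`` per opposed base pair
(min(a, b) of them) plus an affine gap for the length difference. Unpaired
miRNA nucleotides outside the outermost pairs cost ``end`` each (a mild
dangling-end charge); target overhangs are free (local on the target).

Internal-loop penalties are deliberately stiff relative to the pair bonus
(an isolated Watson-Crick pair reachable only across a 1x1 internal loop
nets 2 - 3 < 0 and is excluded), while one-sided bulge extension is cheap,
so predicted duplexes are built from contiguous helices optionally separated
by a target-side bulge — the shapes a nearest-neighbor thermodynamic model
produces for trigger sites. With per-position penalties all at -1, random 3'
sequence against a ~40-nt window supports long chains of isolated pairs and
the 3'-pairing extent that the TDMD/TDTT architecture calls depend on loses
all contrast between planted and background complementarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import check_rna, pair_kind

#: Default additive scoring used throughout the package.
DEFAULT_SCORING = {
    "WC": 2,
    "GU": 0.5,         # wobble pairs are weak; they extend helices only
    "mismatch": -3,    # internal opposed mismatch (loop interior)
    "gap_open": -3,
    "gap_extend": -0.5,  # long one-sided bulges are cheap, as in real sites
    "end": -0.5,       # per unpaired miRNA nt outside the outermost pairs
}

# miRNA functional regions, 1-based guide positions (g-numbering).
SEED = range(2, 9)          # g2-g8
CENTRAL = range(9, 13)      # g9-g12
SUPPLEMENTAL = range(13, 17)  # g13-g16


@dataclass(frozen=True)
class Duplex:
    """Predicted intermolecular duplex between one miRNA and one target window.

    ``pairs`` holds ``(g, t)`` with g the 1-based miRNA position from the 5'
    end and t the 0-based index into ``target_seq`` (window-local, sense
    strand). Pairs are non-crossing: antiparallel strands, so t decreases as
    g increases.
    """

    mirna_id: str
    mirna_seq: str
    target_seq: str
    target_start: int  # transcript coordinate of target_seq[0]
    pairs: tuple[tuple[int, int], ...]
    pair_kinds: tuple[str, ...]
    score: float

    @property
    def paired_g(self) -> frozenset[int]:
        return frozenset(g for g, _ in self.pairs)

    def structure_strings(self) -> tuple[str, str]:
        """Per-position pairing masks: (miRNA 5'->3', target 5'->3')."""
        m = ["."] * len(self.mirna_seq)
        t = ["."] * len(self.target_seq)
        for g, tp in self.pairs:
            m[g - 1] = "("
            t[tp] = ")"
        return "".join(m), "".join(t)


@dataclass(frozen=True)
class PairingArchitecture:
    """Region-wise summary of a duplex and its TDMD/TDTT-relevant calls."""

    seed_match: str  # perfect_2_8 | offset_3_8 | partial | none
    n_seed_pairs: int
    n_central_pairs: int
    n_supplemental_pairs: int
    n_tail_pairs: int
    three_prime_extent: int
    tdtt_prone: bool
    t_position_map: dict[int, int] = field(default_factory=dict)


def _seg_cost(a: int, b: int, scoring: dict) -> float:
    """Cost of an internal unpaired stretch: a miRNA nt against b target nt."""
    if a == 0 and b == 0:
        return 0.0
    mm, go, ge = scoring["mismatch"], scoring["gap_open"], scoring["gap_extend"]
    cost = min(a, b) * mm
    gap = abs(a - b)
    if gap:
        cost += go + (gap - 1) * ge
    return cost


def _end_cost(a: int, scoring: dict) -> float:
    """Dangling-end cost of a miRNA overhang of ``a`` unpaired nucleotides."""
    return a * scoring["end"]


def score_pair_set(
    pairs, mirna: str, target: str, scoring: dict = DEFAULT_SCORING
) -> float:
    """Score an explicit non-crossing pair set under the package scoring.

    ``pairs`` is an iterable of (g, t) as in :class:`Duplex`. Raises if the
    set crosses or pairs non-complementary bases.
    """
    m, n = len(mirna), len(target)
    # Convert to reversed-target coordinates where j increases with g.
    anchors = sorted((g, n - 1 - t) for g, t in pairs)
    score = 0.0
    prev_g, prev_j = 0, -1
    for g, j in anchors:
        if g <= prev_g or j <= prev_j and prev_j >= 0:
            raise ValueError("pair set is crossing or reuses a position")
        kind = pair_kind(mirna[g - 1], target[n - 1 - j])
        if kind is None:
            raise ValueError(f"non-complementary pair (g{g})")
        score += scoring[kind]
        if prev_g == 0:
            score += _end_cost(g - 1, scoring)
        else:
            score += _seg_cost(g - prev_g - 1, j - prev_j - 1, scoring)
        prev_g, prev_j = g, j
    if prev_g == 0:  # empty set: whole miRNA unpaired against free target
        return _end_cost(m, scoring)
    return score + _end_cost(m - prev_g, scoring)


def predict_duplex(
    mirna_seq: str,
    target_window: str,
    scoring: dict = DEFAULT_SCORING,
    mirna_id: str = "",
    target_start: int = 0,
) -> Duplex:
    """Predict the maximum-score non-crossing duplex.

    Global on the miRNA, local on the target window (antiparallel). Ties are
    broken deterministically: more WC pairs, then more seed (g2-g8) pairs,
    then leftmost aligned target start.
    """
    mirna = check_rna(mirna_seq, "miRNA sequence")
    target = check_rna(target_window, "target window")
    if len(mirna) < 7 or len(target) < 7:
        raise ValueError("sequences must be at least 7 nt")
    m, n = len(mirna), len(target)
    rt = target[::-1]

    # Candidate pairs (i = 1-based miRNA pos, j = reversed-target index),
    # processed in (i, j) order so predecessors always precede successors.
    cands: list[tuple[int, int, str]] = []
    for i in range(1, m + 1):
        a = mirna[i - 1]
        for j in range(n):
            kind = pair_kind(a, rt[j])
            if kind is not None:
                cands.append((i, j, kind))

    # The DP value is the lexicographic tuple (score, n_wc, n_seed); since
    # all three components are additive along a chain, it is folded into one
    # scalar key E = score*8192 + n_wc*16 + n_seed (exact for integer or
    # coarsely-quantized scoring; n_wc*16 + n_seed < 8192/step). np.argmax
    # returns the first maximizer, making tie resolution deterministic.
    S1, S2 = 8192.0, 16.0
    mm, go, ge = scoring["mismatch"], scoring["gap_open"], scoring["gap_extend"]
    P = len(cands)
    iarr = np.fromiter((c[0] for c in cands), dtype=np.int64, count=P)
    jarr = np.fromiter((c[1] for c in cands), dtype=np.int64, count=P)
    E = np.empty(P)
    back = np.full(P, -1, dtype=np.int64)
    for idx in range(P):
        i, j, kind = cands[idx]
        pe = scoring[kind] * S1 + (S2 if kind == "WC" else 0.0) + (
            1.0 if i in SEED else 0.0
        )
        best_e = pe + _end_cost(i - 1, scoring) * S1
        if idx:
            qi, qj = iarr[:idx], jarr[:idx]
            mask = (qi < i) & (qj < j)
            if mask.any():
                a = i - qi - 1
                b = j - qj - 1
                gap = np.abs(a - b)
                seg = np.minimum(a, b) * mm + np.where(
                    gap > 0, go + (gap - 1) * ge, 0.0
                )
                tot = np.where(mask, E[:idx] + pe + seg * S1, -np.inf)
                q = int(np.argmax(tot))
                if tot[q] > best_e:
                    best_e, back[idx] = tot[q], q
        E[idx] = best_e

    # Termination: chain ends plus the empty pair set. Final tie-break key
    # appends j (prefer largest last j = leftmost original target start).
    final = _end_cost(m, scoring) * S1 * 32768.0
    final_idx = -1
    if P:
        fin = (E + np.array(
            [_end_cost(m - i, scoring) for i, j, _ in cands]
        ) * S1) * 32768.0 + jarr
        q = int(np.argmax(fin))
        if fin[q] > final:
            final, final_idx = fin[q], q

    chain: list[tuple[int, int, str]] = []
    idx = final_idx
    while idx >= 0:
        chain.append(cands[idx])
        idx = int(back[idx])
    chain.reverse()
    pairs = tuple((i, n - 1 - j) for i, j, _ in chain)
    kinds = tuple(k for _, _, k in chain)
    # Exact score recomputed from the selected chain (shared scorer).
    score = score_pair_set(pairs, mirna, target, scoring)
    return Duplex(
        mirna_id=mirna_id,
        mirna_seq=mirna,
        target_seq=target,
        target_start=target_start,
        pairs=pairs,
        pair_kinds=kinds,
        score=score,
    )


def enumerate_best_score(
    mirna: str, target: str, scoring: dict = DEFAULT_SCORING
) -> float:
    """Exhaustive maximum over all non-crossing pair sets (tiny inputs only).

    Brute-force reference for :func:`predict_duplex`; exponential in the
    number of complementary pairs, intended for lengths <= ~9.
    """
    mirna = check_rna(mirna)
    target = check_rna(target)
    n = len(target)
    cands = [
        (i, j)
        for i in range(1, len(mirna) + 1)
        for j in range(n)
        if pair_kind(mirna[i - 1], target[n - 1 - j]) is not None
    ]
    # Non-crossing pair sets are exactly the chains strictly increasing in
    # both (g, j); depth-first enumeration visits every such set once.
    best = score_pair_set([], mirna, target, scoring)

    def visit(chain: list[tuple[int, int]], start: int) -> None:
        nonlocal best
        if chain:
            pairs = [(g, n - 1 - j) for g, j in chain]
            s = score_pair_set(pairs, mirna, target, scoring)
            if s > best:
                best = s
        for idx in range(start, len(cands)):
            g, j = cands[idx]
            if not chain or (g > chain[-1][0] and j > chain[-1][1]):
                chain.append((g, j))
                visit(chain, idx + 1)
                chain.pop()

    visit([], 0)
    return best


def classify_architecture(
    duplex: Duplex,
    mirna_len: int | None = None,
    min_tail3_pairs: int = 2,
    min_three_prime_extent: int = 8,
) -> PairingArchitecture:
    """Classify a duplex into seed-match category and region pair counts.

    ``tdtt_prone`` marks duplexes whose 3' pairing is extensive enough to be
    expected to displace the miRNA 3' end from the Argonaute PAZ domain
    (target-directed tailing/trimming-competent): at least
    ``min_tail3_pairs`` pairs within the last 3 miRNA positions and a total
    3' (g9-end) pairing extent of at least ``min_three_prime_extent``.
    """
    mlen = mirna_len if mirna_len is not None else len(duplex.mirna_seq)
    if mlen < 17:
        raise ValueError("miRNA shorter than 17 nt: region boundaries undefined")
    paired = duplex.paired_g
    wc = {g for (g, _), k in zip(duplex.pairs, duplex.pair_kinds) if k == "WC"}

    if all(g in wc for g in SEED):
        seed_match = "perfect_2_8"
    elif all(g in paired for g in range(3, 9)) and 2 not in paired:
        seed_match = "offset_3_8"
    elif sum(g in paired for g in SEED) >= 4:
        seed_match = "partial"
    else:
        seed_match = "none"

    n_seed = sum(g in paired for g in SEED)
    n_central = sum(g in paired for g in CENTRAL)
    n_supp = sum(g in paired for g in SUPPLEMENTAL)
    n_tail = sum(g in paired for g in range(17, mlen + 1))
    extent = sum(g in paired for g in range(9, mlen + 1))
    last3 = sum(g in paired for g in range(mlen - 2, mlen + 1))
    tdtt = last3 >= min_tail3_pairs and extent >= min_three_prime_extent

    tmap: dict[int, int] = {}
    if any(g in SEED for g in paired):
        tmap = map_t_positions(duplex, mirna_len=mlen)
    return PairingArchitecture(
        seed_match=seed_match,
        n_seed_pairs=n_seed,
        n_central_pairs=n_central,
        n_supplemental_pairs=n_supp,
        n_tail_pairs=n_tail,
        three_prime_extent=extent,
        tdtt_prone=tdtt,
        t_position_map=tmap,
    )


def map_t_positions(
    duplex: Duplex, mirna_len: int | None = None, extend_to: int = 35
) -> dict[int, int]:
    """Trigger coordinates opposite each miRNA position (t-numbering).

    Under the seed-anchored register, t_i is the trigger nucleotide opposite
    miRNA position i; indices past the miRNA 3' end continue 5'-ward
    (upstream) along the trigger with unit steps, so e.g. t35 lies 27 nt
    upstream of t8. Returns transcript coordinates (window-local target
    index + ``target_start``), extrapolated even across unpaired positions.
    """
    mlen = mirna_len if mirna_len is not None else len(duplex.mirna_seq)
    seed_pairs = [(g, t) for g, t in duplex.pairs if g in SEED]
    if not seed_pairs:
        raise ValueError("duplex has no seed pair: t-register undefined")
    g0, t0 = min(seed_pairs)
    return {
        i: duplex.target_start + t0 - (i - g0)
        for i in range(1, max(extend_to, mlen) + 1)
    }
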