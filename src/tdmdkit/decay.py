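"""Count-table normalization, fold changes, and decay-level inference.

Small-RNA count tables are normalized with size factors computed from a
designated normalizer feature class (total mapped reads, piRNAs, or synthetic
spike-ins), on the assumption that the normalizer class is unaffected by the
perturbation under study. Differential abundance is a normalized fold change
with a label-permutation p-value and Benjamini-Hochberg adjustment.

The guide/passenger contrast distinguishes decay-level from biogenesis-level
effects: a perturbation acting on mature-miRNA decay stabilizes the
Argonaute-loaded guide strand only, whereas transcription- or
biogenesis-level effects move both strands of the duplex.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gmean
from statsmodels.stats.multitest import multipletests

FEATURE_CLASSES = ("mirna_guide", "mirna_passenger", "pirna", "spikein")


class NormalizationError(ValueError):
    pass


@dataclass
class CountTable:
    """Feature x sample integer counts with class labels and sample metadata.

    ``counts``: DataFrame indexed by feature id, one column per sample.
    ``classes``: Series feature id -> class (one of FEATURE_CLASSES).
    ``samples``: DataFrame indexed by sample id with columns
    genotype / stage / replicate.
    """

    counts: pd.DataFrame
    classes: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.classes.unique()) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if not self.classes.index.equals(self.counts.index):
            self.classes = self.classes.reindex(self.counts.index)
            if self.classes.isna().any():
                raise ValueError("every feature needs exactly one class")

    def sample_ids(self, **criteria: str) -> list[str]:
        """Sample ids whose metadata match all given column=value criteria."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            mask &= self.samples[col] == val
        return list(self.samples.index[mask])

    def concat(self, other: "CountTable") -> "CountTable":
        counts = pd.concat([self.counts, other.counts], axis=1)
        return CountTable(counts, self.classes, pd.concat([self.samples, other.samples]))

    def write_tsv(self, counts_path: str | Path, manifest_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "class", self.classes)
        out.to_csv(counts_path, sep="\t", index_label="feature")
        self.samples.to_csv(manifest_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, counts_path: str | Path, manifest_path: str | Path) -> "CountTable":
        df = pd.read_csv(counts_path, sep="\t", index_col="feature")
        classes = df.pop("class")
        samples = pd.read_csv(manifest_path, sep="\t", index_col="sample")
        return cls(df, classes, samples)


@dataclass(frozen=True)
class FoldChangeRecord:
    feature: str
    base_mean: float
    log2fc: float
    p_perm: float | None
    q: float | None


def compute_size_factors(table: CountTable, normalizer_class: str = "total") -> pd.Series:
    """Per-sample size factors from the normalizer class totals.

    factor_s = (class total in s) / geometric mean of class totals, so the
    factors have geometric mean 1 and dividing counts by them preserves the
    overall scale. ``normalizer_class`` is one of ``total``, ``pirna``,
    ``spikein`` (``total`` uses all features).
    """
    if normalizer_class == "total":
        totals = table.counts.sum(axis=0)
    elif normalizer_class in FEATURE_CLASSES:
        totals = table.counts.loc[table.classes == normalizer_class].sum(axis=0)
    else:
        raise ValueError(f"unknown normalizer class {normalizer_class!r}")
    zero = totals.index[totals <= 0]
    if len(zero):
        raise NormalizationError(
            f"normalizer class {normalizer_class!r} has zero total in "
            f"sample(s) {list(zero)}"
        )
    return totals / gmean(totals.to_numpy(dtype=float))


def normalize_counts(table: CountTable, normalizer_class: str = "total") -> pd.DataFrame:
    return table.counts / compute_size_factors(table, normalizer_class)


def _perm_pvalues(
    normd: pd.DataFrame,
    a_ids: list[str],
    b_ids: list[str],
    pseudocount: float,
    max_exhaustive: int = 5040,
    n_random: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p for |log2fc| under relabeling of samples within the contrast.

    All distinct group assignments are enumerated when their number is at
    most ``max_exhaustive`` (the observed labeling included); otherwise
    ``n_random`` random assignments are drawn with a fixed seed. p-values are
    therefore discrete with resolution 1/n_assignments, and significance
    calls downstream use ``p <= alpha``.
    """
    ids = a_ids + b_ids
    k = len(b_ids)
    mat = normd[ids].to_numpy(dtype=float)
    n_comb = math.comb(len(ids), k)
    if n_comb <= max_exhaustive:
        combos = list(itertools.combinations(range(len(ids)), k))
    else:
        rng = np.random.default_rng(seed)
        combos = [
            tuple(rng.choice(len(ids), size=k, replace=False)) for _ in range(n_random)
        ]
    obs = None
    stats = np.empty((len(combos), mat.shape[0]))
    all_idx = np.arange(len(ids))
    b_obs = tuple(range(len(a_ids), len(ids)))
    for c, combo in enumerate(combos):
        b_idx = np.array(combo)
        a_idx = np.setdiff1d(all_idx, b_idx)
        stat = np.abs(
            np.log2(
                (mat[:, b_idx].mean(axis=1) + pseudocount)
                / (mat[:, a_idx].mean(axis=1) + pseudocount)
            )
        )
        stats[c] = stat
        if tuple(sorted(combo)) == b_obs:
            obs = stat
    if obs is None:  # random sampling may miss the identity assignment
        obs = np.abs(
            np.log2(
                (mat[:, len(a_ids):].mean(axis=1) + pseudocount)
                / (mat[:, : len(a_ids)].mean(axis=1) + pseudocount)
            )
        )
    return (stats >= obs[None, :] - 1e-12).mean(axis=0)


def fold_changes(
    table: CountTable,
    contrast: tuple[list[str], list[str]],
    normalizer_class: str = "total",
    pseudocount: float = 0.5,
    base_mean_min: float = 10.0,
    permute: bool = True,
    seed: int = 0,
    feature_classes: tuple[str, ...] | None = None,
) -> list[FoldChangeRecord]:
    """Normalized log2 fold changes (group b over group a) with permutation p.

    Features with base mean (mean normalized count over all samples in the
    contrast) below ``base_mean_min`` are excluded. With fewer than two
    replicates per group the permutation p is omitted. ``feature_classes``
    restricts testing (and the multiple-testing family) to those classes —
    e.g. test miRNA strands only while piRNAs serve as normalizers.
    """
    a_ids, b_ids = contrast
    if not a_ids or not b_ids:
        raise ValueError("both contrast groups must be non-empty")
    normd = normalize_counts(table, normalizer_class)
    if feature_classes is not None:
        normd = normd.loc[table.classes.isin(feature_classes)]
    base_mean = normd[a_ids + b_ids].mean(axis=1)
    keep = base_mean >= base_mean_min
    normd = normd.loc[keep]
    log2fc = np.log2(
        (normd[b_ids].mean(axis=1) + pseudocount)
        / (normd[a_ids].mean(axis=1) + pseudocount)
    )
    do_perm = permute and min(len(a_ids), len(b_ids)) >= 2
    if do_perm:
        p = _perm_pvalues(normd, a_ids, b_ids, pseudocount, seed=seed)
        q = multipletests(p, method="fdr_bh")[1]
    else:
        p = q = [None] * keep.sum()
    return [
        FoldChangeRecord(feat, float(base_mean[feat]), float(lfc), pv, qv)
        for feat, lfc, pv, qv in zip(normd.index, log2fc, p, q)
    ]


def fold_change_frame(records: list[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature, r.base_mean, r.log2fc, r.p_perm, r.q) for r in records],
        columns=["feature", "base_mean", "log2fc", "p_perm", "q"],
    ).set_index("feature")


def decay_amplitude(
    embryo_table: CountTable,
    l1_table: CountTable,
    features: list[str],
    normalizer_class: str = "total",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature embryo->L1 log2 amplitude (negative = decay).

    Both stage tables must be normalized with the same normalizer class.
    Features missing from either stage are flagged (``missing`` column), not
    silently dropped.
    """
    # one size-factor fit across both stages: per-table factors would leave
    # the two stages on different scales (library composition shifts)
    combined = embryo_table.concat(l1_table)
    normd = normalize_counts(combined, normalizer_class)
    ne = normd[embryo_table.counts.columns].mean(axis=1)
    nl = normd[l1_table.counts.columns].mean(axis=1)
    rows = []
    for feat in features:
        missing = feat not in ne.index or feat not in nl.index
        if missing:
            rows.append((feat, np.nan, True))
        else:
            amp = math.log2((nl[feat] + pseudocount) / (ne[feat] + pseudocount))
            rows.append((feat, amp, False))
    return pd.DataFrame(rows, columns=["feature", "log2_amplitude", "missing"]).set_index(
        "feature"
    )


def strand_level_inference(
    guide_fc: FoldChangeRecord,
    passenger_fc: FoldChangeRecord,
    fc_min: float = 1.5,
    passenger_max: float = 1.3,
    alpha: float = 0.05,
) -> str:
    """Call decay-level vs biogenesis-level from the guide/passenger contrast.

    decay_level: guide stabilized (fold change >= fc_min, q <= alpha) while
    the passenger strand is flat (< passenger_max). biogenesis_level: both
    strands up. Anything else: no_call.
    """
    g_up = 2 ** guide_fc.log2fc >= fc_min and guide_fc.q is not None and guide_fc.q <= alpha
    p_fc = 2 ** passenger_fc.log2fc
    p_up = p_fc >= fc_min and passenger_fc.q is not None and passenger_fc.q <= alpha
    if g_up and p_fc < passenger_max:
        return "decay_level"
    if g_up and p_up:
        return "biogenesis_level"
    return "no_call"


def pathway_congruence(
    fc_a: float, fc_b: float, fc_double: float, tol_log2: float = 0.5
) -> str:
    """Classify single- vs double-mutant epistasis on log2 fold changes.

    same_pathway: the double mutant phenocopies the stronger single mutant.
    additive: the double mutant matches the sum of the singles (two
    independent mechanisms). Otherwise intermediate.
    """
    if abs(fc_double - max(fc_a, fc_b)) <= tol_log2:
        return "same_pathway"
    if abs(fc_double - (fc_a + fc_b)) <= tol_log2:
        return "additive"
    return "intermediate"
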