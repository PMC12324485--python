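"""Absolute quantification and trigger stoichiometry.

qPCR standard curves convert Ct values to absolute copies per ng of total
RNA; from these, the module computes how many miRNA molecules are lost per
molecule of trigger lncRNA (the trigger's catalytic potency), deconvolves a
peak expression level from a stage-mixed sample, and bins smFISH spot
intensities into per-embryo molecule counts against a single-molecule
reference intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class CurveQualityError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of Ct on log10(copies) for a dilution series."""

    slope: float  # Ct per log10 copies, negative
    intercept: float  # Ct at 1 copy
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 1.0 = perfect doubling."""
        return 10 ** (-1 / self.slope) - 1


def fit_standard_curve(dilution_copies, ct_values) -> StandardCurve:
    """OLS standard curve from >= 4 dilution points spanning >= 3 decades."""
    copies = np.asarray(dilution_copies, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if copies.size < 4:
        raise CurveQualityError("standard curve needs at least 4 dilution points")
    if (copies <= 0).any():
        raise CurveQualityError("standard copies must be positive")
    lg = np.log10(copies)
    if lg.max() - lg.min() < 3:
        raise CurveQualityError("dilution series must span at least 3 decades")
    res = stats.linregress(lg, ct)
    if res.slope >= 0:
        raise CurveQualityError("standard-curve slope must be negative")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify_copies(ct: float, curve: StandardCurve, input_ng: float) -> float:
    """Copies per ng of input RNA from one Ct value."""
    if not math.isfinite(ct):
        raise ValueError("ct must be finite")
    if input_ng <= 0:
        raise ValueError("input_ng must be positive")
    copies_per_reaction = 10 ** ((ct - curve.intercept) / curve.slope)
    return copies_per_reaction / input_ng


def excess_family_molecules(
    ref_copies_wt: float,
    member_ratios: dict[str, float],
    fold_changes: dict[str, float],
) -> float:
    """Excess family copies/ng in the mutant vs wild type.

    ``member_ratios`` gives each member's wild-type abundance relative to the
    absolutely-quantified reference member (reference ratio = 1);
    ``fold_changes`` the per-member mutant/wild-type ratio. excess =
    sum_i ratio_i * ref_copies_wt * (FC_i - 1).
    """
    missing = set(member_ratios) ^ set(fold_changes)
    if missing:
        raise KeyError(f"member entries missing from ratios or folds: {sorted(missing)}")
    if any(r <= 0 for r in member_ratios.values()):
        raise ValueError("member ratios must be positive")
    if any(f < 0 for f in fold_changes.values()):
        raise ValueError("fold changes must be non-negative")
    return sum(
        member_ratios[m] * ref_copies_wt * (fold_changes[m] - 1.0)
        for m in member_ratios
    )


def molecules_per_trigger(
    excess_copies_per_ng: float, trigger_copies_per_ng: float
) -> tuple[float, float]:
    """Molecules of miRNA degraded per molecule of trigger.

    Returns (raw ratio, reported ratio); the reported value is rounded to
    the nearest integer at >= 20 and to one decimal below 20.
    """
    if trigger_copies_per_ng <= 0:
        raise ValueError("trigger copies must be positive")
    raw = excess_copies_per_ng / trigger_copies_per_ng
    reported = float(math.floor(raw + 0.5)) if raw >= 20 else round(raw, 1)
    return raw, reported


def estimate_peak_copies(
    measured_mixed: float, weights, relative_profile
) -> float:
    """Peak expression from a stage-mixed absolute measurement.

    With stage weights w_s (summing to 1) and a temporal profile r_s
    relative to the peak (r_peak = 1), a mixed sample measures
    peak * sum_s w_s r_s; inverting gives the peak estimate.
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(relative_profile, dtype=float)
    if abs(w.sum() - 1) > 1e-6:
        raise ValueError("stage weights must sum to 1")
    denom = float(w @ r)
    if denom <= 0:
        raise ValueError("degenerate mixture: sum of w_s * r_s must be positive")
    return measured_mixed / denom


def smfish_molecule_counts(
    reference_spot_intensities,
    sample_spot_table: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Bin smFISH spot intensities into molecule counts per embryo.

    The single-molecule unit intensity is the median of the reference-stage
    spot intensities (>= 20 spots required); each sample spot is assigned
    max(1, nearest integer of intensity/unit) molecules. Returns a
    per-embryo frame (stage, n_spots, molecules) and the unit intensity.
    """
    ref = np.asarray(reference_spot_intensities, dtype=float)
    if ref.size < 20:
        raise ValueError("need at least 20 reference spots for calibration")
    unit = float(np.median(ref))
    if unit <= 0:
        raise ValueError("calibration failed: unit intensity must be positive")
    df = sample_spot_table.copy()
    df["molecules"] = np.maximum(
        1, np.floor(df["integrated_intensity"] / unit + 0.5).astype(int)
    )
    per_embryo = (
        df.groupby(["embryo_id", "stage"], as_index=False)
        .agg(n_spots=("spot_id", "size"), molecules=("molecules", "sum"))
        .set_index("embryo_id")
    )
    return per_embryo, unit


def stage_fold_change(per_embryo: pd.DataFrame, stage_a: str, stage_b: str) -> float:
    """Ratio of mean per-embryo molecule totals, stage_b over stage_a."""
    means = per_embryo.groupby("stage")["molecules"].mean()
    return float(means[stage_b] / means[stage_a])
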