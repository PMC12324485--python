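"""Size factors, permutation fold changes, and decay-level inference."""

import numpy as np
import pandas as pd
import pytest

from tdmdkit import simulate as S
from tdmdkit.decay import (
    CountTable,
    FoldChangeRecord,
    NormalizationError,
    compute_size_factors,
    decay_amplitude,
    fold_change_frame,
    fold_changes,
    normalize_counts,
    pathway_congruence,
    strand_level_inference,
)
from tdmdkit.simulate import SimConfig


def _table(counts: dict, classes: dict, meta=None):
    df = pd.DataFrame(counts)
    cls = pd.Series({f: classes[f] for f in df.index})
    if meta is None:
        meta = pd.DataFrame(
            [(s, "wild_type", "L1", i + 1) for i, s in enumerate(df.columns)],
            columns=["sample", "genotype", "stage", "replicate"],
        ).set_index("sample")
    return CountTable(df, cls, meta)


class TestSizeFactors:
    def test_equal_totals_give_unit_factors(self):
        t = _table({"s1": [100], "s2": [100]}, {0: "pirna"})
        assert compute_size_factors(t, "pirna").tolist() == pytest.approx([1.0, 1.0])

    def test_factors_from_geometric_mean(self):
        t = _table({"s1": [100], "s2": [400]}, {0: "pirna"})
        assert compute_size_factors(t, "pirna").tolist() == pytest.approx([0.5, 2.0])

    def test_rescaling_one_sample_preserves_normalized_structure(self):
        # tripling one library rescales its factor; normalized counts agree
        # up to the common re-anchoring constant (factors keep gmean 1)
        t = _table({"s1": [100, 50], "s2": [200, 100]}, {0: "pirna", 1: "mirna_guide"})
        n1 = normalize_counts(t, "pirna")
        t2 = _table({"s1": [100, 50], "s2": [600, 300]}, {0: "pirna", 1: "mirna_guide"})
        n2 = normalize_counts(t2, "pirna")
        ratio = n2.values / n1.values
        assert np.allclose(ratio, ratio.flat[0])
        f1 = compute_size_factors(t, "pirna")
        f2 = compute_size_factors(t2, "pirna")
        assert f2["s2"] / f1["s2"] == pytest.approx(3 / (f1["s1"] / f2["s1"]))

    def test_zero_normalizer_total_names_sample(self):
        t = _table({"s1": [100], "s2": [0]}, {0: "spikein"})
        with pytest.raises(NormalizationError, match="s2"):
            compute_size_factors(t, "spikein")

    def test_factors_have_unit_geometric_mean(self):
        t = _table({"a": [10], "b": [90], "c": [300]}, {0: "pirna"})
        f = compute_size_factors(t, "pirna")
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)


class TestFoldChanges:
    def _flat_table(self):
        # equal totals so size factors are 1 and arithmetic is exact
        counts = {
            "a1": [10, 1000, 5], "a2": [10, 1000, 5],
            "b1": [80, 930, 5], "b2": [80, 930, 5],
        }
        return _table(
            counts, {0: "mirna_guide", 1: "pirna", 2: "mirna_guide"},
        )

    def test_log2fc_with_pseudocount(self):
        t = self._flat_table()
        recs = fold_changes(t, (["a1", "a2"], ["b1", "b2"]),
                            normalizer_class="total", permute=False)
        fc = {r.feature: r.log2fc for r in recs}
        assert fc[0] == pytest.approx(np.log2(80.5 / 10.5), abs=1e-6)

    def test_base_mean_filter_excludes_low_features(self):
        t = self._flat_table()
        recs = fold_changes(t, (["a1", "a2"], ["b1", "b2"]),
                            normalizer_class="total", permute=False)
        assert 2 not in {r.feature for r in recs}  # base mean 5 < 10

    def test_normalization_invariance_of_fold_changes(self):
        t = self._flat_table()
        scaled = t.counts.copy()
        scaled["b1"] = scaled["b1"] * 3
        t2 = CountTable(scaled, t.classes, t.samples)
        a = fold_change_frame(fold_changes(t, (["a1", "a2"], ["b1", "b2"]),
                                           normalizer_class="pirna", permute=False))
        b = fold_change_frame(fold_changes(t2, (["a1", "a2"], ["b1", "b2"]),
                                           normalizer_class="pirna", permute=False))
        # exact up to the pseudocount interacting with factor re-anchoring
        assert np.allclose(a.log2fc, b.log2fc, atol=0.05)

    def test_planted_effect_detected_with_q(self, transcriptome):
        _, truth = transcriptome
        cfg = SimConfig(rng_seed=31)
        table = S.simulate_experiment(cfg, truth, stages=("L1",))
        a = table.sample_ids(genotype="wild_type")
        b = table.sample_ids(genotype="decay_null")
        f = fold_change_frame(
            fold_changes(table, (a, b), normalizer_class="pirna",
                         feature_classes=("mirna_guide",))
        )
        g = f.loc[list(truth.member_ids)]
        assert (g.q <= 0.05).all()
        assert (2 ** g.log2fc > 4).all()


class TestDecayAmplitude:
    def _stage_tables(self, embryo, l1):
        meta_e = pd.DataFrame(
            [("e1", "wild_type", "embryo", 1)],
            columns=["sample", "genotype", "stage", "replicate"],
        ).set_index("sample")
        meta_l = pd.DataFrame(
            [("l1", "wild_type", "L1", 1)],
            columns=["sample", "genotype", "stage", "replicate"],
        ).set_index("sample")
        cls = {0: "mirna_guide", 1: "pirna"}
        te = _table({"e1": embryo}, cls, meta_e)
        tl = _table({"l1": l1}, cls, meta_l)
        return te, tl

    def test_equal_means_give_zero(self):
        te, tl = self._stage_tables([8000, 1000], [8000, 1000])
        amp = decay_amplitude(te, tl, [0], normalizer_class="pirna")
        assert amp.loc[0, "log2_amplitude"] == pytest.approx(0.0, abs=1e-6)

    def test_eightfold_decay_is_minus_three(self):
        te, tl = self._stage_tables([8000, 1000], [1000, 1000])
        amp = decay_amplitude(te, tl, [0], normalizer_class="pirna")
        assert amp.loc[0, "log2_amplitude"] == pytest.approx(-3.0, abs=1e-3)

    def test_missing_feature_flagged_not_dropped(self):
        te, tl = self._stage_tables([8000, 1000], [1000, 1000])
        amp = decay_amplitude(te, tl, [0, 99], normalizer_class="pirna")
        assert bool(amp.loc[99, "missing"])

    def test_genotype_amplitude_difference_recovers_decay_fold(self, transcriptome):
        _, truth = transcriptome
        diffs = []
        for seed in range(3):
            cfg = SimConfig(rng_seed=60 + seed)
            amps = {}
            for gt in ("wild_type", "decay_null"):
                te = S.simulate_count_tables(cfg, truth, gt, "embryo")
                tl = S.simulate_count_tables(cfg, truth, gt, "L1")
                amp = decay_amplitude(te, tl, list(truth.member_ids),
                                      normalizer_class="pirna")
                amps[gt] = amp["log2_amplitude"]
            diffs.append((amps["decay_null"] - amps["wild_type"]).mean())
        assert np.mean(diffs) == pytest.approx(np.log2(7.1), abs=0.3)


class TestInferenceRules:
    def _fc(self, feature, fc, q):
        return FoldChangeRecord(feature, 100.0, float(np.log2(fc)), 0.01, q)

    def test_guide_up_passenger_flat_is_decay_level(self):
        call = strand_level_inference(self._fc("g", 7.1, 0.01), self._fc("g*", 1.0, 0.9))
        assert call == "decay_level"

    def test_both_strands_up_is_biogenesis_level(self):
        call = strand_level_inference(self._fc("g", 3.0, 0.01), self._fc("g*", 3.0, 0.01))
        assert call == "biogenesis_level"

    def test_insignificant_guide_is_no_call(self):
        call = strand_level_inference(self._fc("g", 7.1, 0.5), self._fc("g*", 1.0, 0.9))
        assert call == "no_call"

    def test_synthetic_contrast_calls_all_members_decay_level(self, transcriptome):
        _, truth = transcriptome
        cfg = SimConfig(rng_seed=33)
        table = S.simulate_experiment(cfg, truth, stages=("L1",))
        a = table.sample_ids(genotype="wild_type")
        b = table.sample_ids(genotype="decay_null")
        guides_fc = {
            r.feature: r
            for r in fold_changes(table, (a, b), normalizer_class="pirna",
                                  feature_classes=("mirna_guide",))
        }
        pass_fc = {
            r.feature: r
            for r in fold_changes(table, (a, b), normalizer_class="pirna",
                                  feature_classes=("mirna_passenger",))
        }
        for gid in truth.member_ids:
            call = strand_level_inference(guides_fc[gid], pass_fc[gid + "*"])
            assert call == "decay_level", gid

    @pytest.mark.parametrize(
        "fa,fb,fd,expected",
        [
            (2.8, 2.5, 2.9, "same_pathway"),
            (1.0, 1.0, 2.0, "additive"),
            (1.0, 1.0, 3.5, "intermediate"),
        ],
    )
    def test_pathway_congruence_rules(self, fa, fb, fd, expected):
        assert pathway_congruence(fa, fb, fd) == expected

    def test_same_pathway_truth_called_for_all_members(self, transcriptome):
        # double mutant phenocopies the stronger single mutant
        _, truth = transcriptome
        rng = np.random.default_rng(0)
        for gid in truth.member_ids:
            fc_a = np.log2(truth.decay_folds[gid]) + rng.normal(0, 0.1)
            fc_b = np.log2(truth.decay_folds[gid]) * 0.9 + rng.normal(0, 0.1)
            fc_double = max(fc_a, fc_b) + rng.normal(0, 0.1)
            assert pathway_congruence(fc_a, fc_b, fc_double) == "same_pathway"


class TestCountTableIO:
    def test_tsv_roundtrip(self, tmp_path, cfg, transcriptome):
        _, truth = transcriptome
        table = S.simulate_count_tables(cfg, truth, "wild_type", "L1")
        table.write_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = CountTable.read_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert back.counts.equals(table.counts)
        assert back.classes.equals(table.classes)
        assert back.samples.equals(table.samples)
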