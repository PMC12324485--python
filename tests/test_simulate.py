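"""Generator invariants: determinism, planted structure, parameter recovery."""

import numpy as np
import pytest

from tdmdkit import simulate as S
from tdmdkit._seq import revcomp_rna
from tdmdkit.chimera import preprocess_reads
from tdmdkit.duplex import classify_architecture, predict_duplex
from tdmdkit.mirna import guides
from tdmdkit.simulate import InvalidConfigError, SimConfig


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"family_size": 1},
            {"mirna_length": 17},
            {"enrichment_lambda": 0.5},
            {"decay_fold": 0.5},
            {"trim_prob": 0.7, "tail_prob": 0.5},
            {"qpcr_efficiency": 1.3},
            {"hybrid_depth": 0},
            {"trigger_site1_3p_pairing": (12, 2)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            SimConfig(**kwargs)


class TestMiRNAFamily:
    def test_guides_share_seed_and_diverge_in_three_prime(self, family):
        gs = guides(family)
        assert len(gs) == 8
        seeds = {g.seed for g in gs}
        assert len(seeds) == 1
        for i, a in enumerate(gs):
            for b in gs[i + 1 :]:
                ta, tb = a.sequence[8:], b.sequence[8:]
                diff = sum(x != y for x, y in zip(ta, tb))
                assert diff >= 0.30 * len(ta)

    def test_each_guide_has_passenger_following_hairpin_rule(self, family):
        gs = guides(family)
        ps = {r.id: r for r in family if r.role == "passenger"}
        assert len(ps) == len(gs)
        for g in gs:
            p = ps[g.id + "*"]
            assert p.sequence[:-2] == revcomp_rna(g.sequence[2:])
            assert len(p.sequence) == len(g.sequence)

    def test_contexts_present_for_isoform_analysis(self, family):
        assert all(len(g.downstream_context) >= 10 for g in guides(family))

    def test_deterministic_under_seed(self, cfg):
        a = S.make_mirna_family(cfg)
        b = S.make_mirna_family(SimConfig(rng_seed=cfg.rng_seed))
        assert [(r.id, r.sequence, r.downstream_context) for r in a] == [
            (r.id, r.sequence, r.downstream_context) for r in b
        ]


class TestTranscriptome:
    def test_all_members_have_perfect_seed_at_site1(self, family, transcriptome):
        transcripts, truth = transcriptome
        trig = transcripts[truth.trigger_transcript_id]
        s, e = truth.site1_span
        window = trig[s : e + 3].replace("T", "U")
        for g in guides(family):
            arch = classify_architecture(predict_duplex(g.sequence, window))
            assert arch.seed_match == "perfect_2_8", g.id

    def test_site2_member_has_offset_seed_and_extensive_three_prime(
        self, family, transcriptome
    ):
        transcripts, truth = transcriptome
        trig = transcripts[truth.trigger_transcript_id]
        s, e = truth.site2_span
        window = trig[max(0, s - 3) : e + 3].replace("T", "U")
        member = next(g for g in guides(family) if g.id == truth.site2_member_id)
        d = predict_duplex(member.sequence, window)
        paired = d.paired_g
        assert 2 not in paired
        assert all(g in paired for g in range(3, 9))
        assert sum(g in paired for g in range(9, 23)) >= 8

    def test_decoy_seed_site_is_seed_only(self, family, transcriptome):
        transcripts, truth = transcriptome
        tid, (s, e) = truth.decoy_sites[0]
        window = transcripts[tid][s:e].replace("T", "U")
        arch = classify_architecture(predict_duplex(guides(family)[0].sequence, window))
        assert arch.n_supplemental_pairs == 0
        assert arch.n_tail_pairs == 0

    def test_truth_spans_inside_trigger_and_disjoint(self, transcriptome):
        transcripts, truth = transcriptome
        n = len(transcripts[truth.trigger_transcript_id])
        for s, e in (truth.site1_span, truth.site2_span):
            assert 0 <= s < e <= n
        assert truth.site1_span[1] <= truth.site2_span[0]


class TestChimericLibraries:
    def test_lambda_one_gives_equal_trigger_rpm_expectation(self, family, transcriptome):
        transcripts, truth = transcriptome
        cfg = SimConfig(rng_seed=11, enrichment_lambda=1.0, n_replicates=1)
        inter = S.interaction_table(family, transcripts, truth)
        study = S.simulate_hybrid_study(cfg, family, transcripts, truth, inter)

        def trig_frac(tab):
            f = tab.frame
            return (
                f.loc[f.transcript == truth.trigger_transcript_id, "count"].sum()
                / tab.total_hybrids
            )

        p_wt = trig_frac(study["wild_type"][0])
        p_mut = trig_frac(study["decay_null"][0])
        pooled = (p_wt + p_mut) / 2
        sd = np.sqrt(2 * pooled * (1 - pooled) / cfg.hybrid_depth)
        assert abs(p_wt - p_mut) <= 3 * sd

    def test_lambda_four_trigger_rpm_ratio_in_range(self, family, transcriptome):
        transcripts, truth = transcriptome
        cfg = SimConfig(rng_seed=13, enrichment_lambda=4.0, n_replicates=1)
        inter = S.interaction_table(family, transcripts, truth)
        study = S.simulate_hybrid_study(cfg, family, transcripts, truth, inter)

        def trig_rpm(tab):
            f = tab.frame
            return f.loc[f.transcript == truth.trigger_transcript_id, "rpm"].sum()

        ratio = trig_rpm(study["decay_null"][0]) / trig_rpm(study["wild_type"][0])
        assert 3.0 <= ratio <= 5.0

    def test_no_pcr_duplication_gives_unique_reads(self, family, transcriptome):
        transcripts, truth = transcriptome
        cfg = SimConfig(rng_seed=5, hybrid_depth=500, pcr_duplication_mean=0.0)
        inter = S.interaction_table(family, transcripts, truth)
        lib = S.simulate_chimeric_reads(
            cfg, family, transcripts, truth, "wild_type", interactions=inter
        )
        seqs = [s for _, s in lib.reads]
        assert len(seqs) == len(set(seqs)) == lib.n_unique_molecules

    def test_umi_aware_collapse_recovers_molecule_count(self, family, transcriptome):
        transcripts, truth = transcriptome
        cfg = SimConfig(rng_seed=5, hybrid_depth=800, pcr_duplication_mean=2.0)
        inter = S.interaction_table(family, transcripts, truth)
        lib = S.simulate_chimeric_reads(
            cfg, family, transcripts, truth, "wild_type", interactions=inter
        )
        _, log = preprocess_reads(lib.reads, cfg.adapter3)
        assert log["collapsed"] == lib.n_unique_molecules

    def test_read_rendering_deterministic(self, family, transcriptome):
        transcripts, truth = transcriptome
        cfg = SimConfig(rng_seed=5, hybrid_depth=300)
        inter = S.interaction_table(family, transcripts, truth)
        a = S.simulate_chimeric_reads(
            cfg, family, transcripts, truth, "wild_type", interactions=inter
        )
        b = S.simulate_chimeric_reads(
            cfg, family, transcripts, truth, "wild_type", interactions=inter
        )
        assert a.reads == b.reads


class TestCountTables:
    def test_passenger_log2fc_centers_on_zero(self, transcriptome):
        _, truth = transcriptome
        from tdmdkit.decay import fold_change_frame, fold_changes

        vals = []
        for seed in range(4):
            cfg = SimConfig(rng_seed=50 + seed)
            table = S.simulate_experiment(cfg, truth, stages=("L1",))
            a = table.sample_ids(genotype="wild_type")
            b = table.sample_ids(genotype="decay_null")
            f = fold_change_frame(
                fold_changes(table, (a, b), normalizer_class="pirna", permute=False)
            )
            pas = [p for p in truth.passenger_ids if p in f.index]
            vals.append(f.loc[pas, "log2fc"].mean())
        assert abs(np.mean(vals)) < 0.15

    def test_spikeins_and_pirnas_are_genotype_independent(self, cfg, transcriptome):
        # raw counts shift with library composition (guides are stabilized),
        # but normalized spike-in/piRNA levels must be genotype-independent
        from tdmdkit.decay import normalize_counts

        _, truth = transcriptome
        table = S.simulate_count_tables(cfg, truth, "wild_type", "L1").concat(
            S.simulate_count_tables(cfg, truth, "decay_null", "L1")
        )
        normd = normalize_counts(table, "pirna")
        wt_ids = table.sample_ids(genotype="wild_type")
        mut_ids = table.sample_ids(genotype="decay_null")
        for cls in ("spikein", "pirna"):
            sub = normd.loc[table.classes == cls]
            a = sub[wt_ids].to_numpy().mean()
            b = sub[mut_ids].to_numpy().mean()
            assert abs(np.log2(b / a)) < 0.2


class TestIsoformReads:
    def test_zero_probabilities_give_all_canonical(self, family, transcriptome):
        _, truth = transcriptome
        cfg = SimConfig(rng_seed=3, trim_prob=0.0, tail_prob=0.0, isoform_depth=200)
        _, truth0 = S.make_transcriptome(cfg, S.make_mirna_family(cfg))
        reads = S.simulate_isoform_reads(cfg, family, truth0, "wild_type")
        by_id = {g.id: g for g in guides(family)}
        for mid, rs in reads.items():
            assert all(r == by_id[mid].sequence for r in rs)

    def test_pure_u_tail_distribution_recovered(self, family):
        from tdmdkit.isomir import assign_isoform

        cfg = SimConfig(
            rng_seed=3, trim_prob=0.0, tail_prob=1.0, elevated_trim_prob=0.0,
            isoform_depth=300, tail_nt_dist={"U": 1.0},
        )
        fam0 = S.make_mirna_family(cfg)
        _, truth0 = S.make_transcriptome(cfg, fam0)
        reads = S.simulate_isoform_reads(cfg, fam0, truth0, "wild_type")
        by_id = {g.id: g for g in guides(fam0)}
        for mid, rs in reads.items():
            for r in rs:
                rec = assign_isoform(r, by_id[mid])
                assert set(rec.tail_seq) <= {"U"}


class TestQuantFixtures:
    def test_noise_free_ct_spacing_at_perfect_efficiency(self, transcriptome):
        _, truth = transcriptome
        cfg = SimConfig(rng_seed=1, qpcr_efficiency=1.0, qpcr_ct_sd=0.0)
        qpcr, _ = S.simulate_quant_data(cfg, truth)
        std = qpcr[(qpcr.species == "trigger") & (qpcr.role == "standard")]
        cts = std.groupby("copies")["ct"].mean().sort_index().to_numpy()
        steps = -np.diff(cts)
        assert np.allclose(steps, 1 / np.log10(2), atol=1e-9)

    def test_reference_stage_unit_intensity_recovered(self, cfg, transcriptome):
        _, truth = transcriptome
        _, spots = S.simulate_quant_data(cfg, truth)
        ref = spots.loc[spots.stage == "bean", "integrated_intensity"]
        assert abs(np.median(ref) / cfg.spot_unit_intensity - 1) < 0.02

    def test_quant_tables_deterministic(self, cfg, transcriptome):
        _, truth = transcriptome
        q1, s1 = S.simulate_quant_data(cfg, truth)
        q2, s2 = S.simulate_quant_data(cfg, truth)
        assert q1.equals(q2) and s1.equals(s2)
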