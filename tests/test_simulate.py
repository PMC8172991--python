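"""Synthetic control material: determinism, composition, and statistical
faithfulness of the read-sampling model."""

import numpy as np
import pytest

from panelval import io as pio
from panelval.concordance import classify_small_variants, match_fusion
from panelval.filtering import FILTER_ONE, apply_reporting_filter
from panelval.lod import analytic_detection_prob
from panelval.model import SmallVariant, TruthSet, VariantCallSet
from panelval.simulate import (
    SimulationConfig,
    simulate_cnv_calls,
    simulate_fusion_calls,
    simulate_observed_calls,
    simulate_replicates,
    simulate_target_space,
    simulate_truth,
)


def small_cfg(**overrides):
    base = dict(seed=5, n_small_variants=60, n_genes=8)
    base.update(overrides)
    return SimulationConfig(**base)


class TestTargetSpace:
    def test_deterministic_under_seed(self):
        cfg = small_cfg()
        a = simulate_target_space(cfg)
        b = simulate_target_space(cfg)
        assert a.intervals == b.intervals
        assert a.reference == b.reference

    def test_transcript_count_and_disjointness(self):
        cfg = small_cfg(n_genes=10)
        target = simulate_target_space(cfg)
        tx = {iv.transcript_id for iv in target.intervals}
        assert len(tx) == 10
        ivs = sorted(target.intervals, key=lambda iv: iv.start)
        assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_contains_long_homopolymer(self):
        target = simulate_target_space(small_cfg())
        seq = target.reference["chr1"]
        assert "A" * 9 in seq  # exercises the indel reference-repeat filter


class TestTruth:
    def test_default_composition(self, default_cfg, default_truth):
        """Default control content: 500 variants across 53 gene labels with
        all five variant classes, and the 16-event fusion panel with one
        entry at 6 copies/ng."""
        tv = default_truth.small_variants
        assert len(tv) == 500
        assert len({v.gene for v in tv}) == 53
        assert {v.vclass for v in tv} == {
            "SNV", "MNV", "insertion", "deletion", "complex"
        }
        assert len(default_truth.fusions) == 16
        kinds = [f.event_kind for f in default_truth.fusions]
        assert kinds.count("fusion") == 14 and kinds.count("splice_variant") == 2
        assert sorted(f.copies_per_ng for f in default_truth.fusions)[0] == 6.0

    def test_variant_keys_unique_and_in_target(self, default_truth, default_target):
        keys = [v.key for v in default_truth.small_variants]
        assert len(keys) == len(set(keys))
        for v in default_truth.small_variants:
            assert any(
                iv.contains_pos1(v.chrom, v.pos) for iv in default_target.intervals
            )

    def test_zero_variants(self):
        cfg = small_cfg(n_small_variants=0)
        target = simulate_target_space(cfg)
        assert simulate_truth(cfg, target).small_variants == []

    def test_pure_snv_mix(self):
        cfg = small_cfg(variant_class_mix={"SNV": 1.0})
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        assert {v.vclass for v in truth.small_variants} == {"SNV"}

    def test_target_too_small_raises(self):
        cfg = small_cfg(n_small_variants=5000)
        target = simulate_target_space(cfg)
        with pytest.raises(ValueError, match="too small"):
            simulate_truth(cfg, target)

    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            small_cfg(variant_class_mix={"SNV": 0.5})


class TestObservedCalls:
    def test_deterministic_and_roundtrips_through_io(self, tmp_path):
        cfg = small_cfg()
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        cs1, prof1 = simulate_observed_calls(truth, cfg, target, seed_stream=1)
        cs2, prof2 = simulate_observed_calls(truth, cfg, target, seed_stream=1)
        assert cs1.key_set() == cs2.key_set()
        assert np.array_equal(prof1.depths, prof2.depths)
        # byte-identical files under a fixed seed
        for i, cs in enumerate((cs1, cs2)):
            pio.write_vcf(cs, tmp_path / f"v{i}.vcf")
            pio.write_coverage_tsv(prof1, tmp_path / f"d{i}.tsv")
        assert (tmp_path / "v0.vcf").read_bytes() == (tmp_path / "v1.vcf").read_bytes()
        assert (tmp_path / "d0.tsv").read_bytes() == (tmp_path / "d1.tsv").read_bytes()
        back = pio.read_vcf(tmp_path / "v0.vcf")
        assert back.key_set() == cs1.key_set()

    def test_zero_fraction_yields_no_true_calls(self):
        cfg = small_cfg(fp_rate=0.0)
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        cs, _ = simulate_observed_calls(truth, cfg, target, dilution_fraction=0.0)
        assert cs.key_set().isdisjoint(truth.small_variant_keys())
        assert len(cs) == 0  # fp_rate 0: nothing at all

    def test_perfect_recovery_at_high_signal(self):
        """No spurious calls, undiluted, deep coverage, VAFs well above the
        filter: classification against truth gives FP=0 and FN=0."""
        cfg = small_cfg(
            fp_rate=0.0, vaf_bulk=(0.3, 0.5), vaf_tail_weight=0.0,
            depth_mean=1000.0,
        )
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        cs, prof = simulate_observed_calls(truth, cfg, target)
        filtered = VariantCallSet(
            cs.sample_id,
            [v for v in cs.variants if apply_reporting_filter(v, FILTER_ONE)],
        )
        c = classify_small_variants(
            filtered, truth, target.intervals, prof, min_depth=FILTER_ONE.min_depth
        )
        assert (c.fp, c.fn, c.no_call) == (0, 0, 0)
        assert c.tp == len(truth.small_variants)

    def test_detection_frequency_matches_closed_form(self):
        """A 5%-VAF variant at fixed depth 250 is detected (under the 100x /
        2.6% reporting filter) at the binomial-tail rate, within 3 standard
        errors across 500 independent draws."""
        cfg = small_cfg(
            n_small_variants=0, depth_mean=250.0, depth_cv=0.0, fp_rate=0.0,
        )
        target = simulate_target_space(cfg)
        variant = SmallVariant("chr1", 150, target.ref_base("chr1", 150),
                               "T" if target.ref_base("chr1", 150) != "T" else "G",
                               vaf=0.05)
        truth = TruthSet(small_variants=[variant])
        p = analytic_detection_prob(0.05, 250, 7, FILTER_ONE.min_vaf)
        n = 500
        detected = 0
        for s in range(n):
            cs, _ = simulate_observed_calls(truth, cfg, target, seed_stream=s)
            detected += any(
                apply_reporting_filter(v, FILTER_ONE) and v.key == variant.key
                for v in cs.variants
            )
        se = (p * (1 - p) / n) ** 0.5
        assert abs(detected / n - p) <= 3 * se

    def test_empirical_ppa_matches_mean_detection_probability(self):
        """End-to-end faithfulness: with fixed depth, the pipeline PPA over
        many seeds matches the truth-set average of the closed-form detection
        probability within 2 standard errors."""
        cfg = small_cfg(depth_cv=0.0, fp_rate=0.0, n_small_variants=40)
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        probs = [
            analytic_detection_prob(v.vaf, int(cfg.depth_mean), 7, FILTER_ONE.min_vaf)
            for v in truth.small_variants
        ]
        n_seeds = 60
        tp = 0
        for s in range(n_seeds):
            cs, prof = simulate_observed_calls(truth, cfg, target, seed_stream=s)
            filtered = VariantCallSet(
                cs.sample_id,
                [v for v in cs.variants if apply_reporting_filter(v, FILTER_ONE)],
            )
            tp += len(filtered.key_set() & truth.small_variant_keys())
        total = n_seeds * len(truth.small_variants)
        expected = sum(probs) / len(probs)
        se = (sum(p * (1 - p) for p in probs) * n_seeds) ** 0.5 / total
        assert abs(tp / total - expected) <= 2 * se + 1e-12


class TestFusionCalls:
    def test_zero_copies_never_emitted(self):
        cfg = small_cfg()
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        silent = [
            type(f)(f.gene_a, f.gene_b, f.expected_exons_a, f.expected_exons_b,
                    0.0, f.event_kind)
            for f in truth.fusions
        ]
        for s in range(20):
            assert simulate_fusion_calls(silent, cfg, seed_stream=s) == []

    def test_low_abundance_fusion_detected_less_often(self):
        """The 6 copies/ng event is detected (as high confidence) less often
        than 13 copies/ng events at equal input, over 500 draws — the Poisson
        tail ordering behind the copies/ng LOD."""
        cfg = small_cfg()
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        low = next(f for f in truth.fusions if f.copies_per_ng == 6.0)
        high = next(f for f in truth.fusions if f.copies_per_ng == 13.0)
        n_low = n_high = 0
        for s in range(500):
            calls = simulate_fusion_calls([low, high], cfg, seed_stream=s)
            by_pair = {(c.gene_a, c.gene_b): c for c in calls}
            lc = by_pair.get((low.gene_a, low.gene_b))
            hc = by_pair.get((high.gene_a, high.gene_b))
            n_low += bool(lc and lc.confidence == "high")
            n_high += bool(hc and hc.confidence == "high")
        assert n_low < n_high

    def test_emitted_breakpoints_match_expected_exons(self):
        cfg = small_cfg(noise=0.0)
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        calls = simulate_fusion_calls(truth.fusions, cfg)
        assert len(calls) == len(truth.fusions)
        for call, ft in zip(calls, truth.fusions):
            assert match_fusion(call, ft)

    def test_displaced_breakpoints_never_match(self):
        cfg = small_cfg(noise=0.0, displace_breakpoints=True)
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        calls = simulate_fusion_calls(truth.fusions, cfg)
        for call, ft in zip(calls, truth.fusions):
            assert not match_fusion(call, ft)


class TestReplicates:
    DESIGN = [
        {"run_id": "R1", "operator_id": "O1", "machine_id": "M1"},
        {"run_id": "R1", "operator_id": "O1", "machine_id": "M1"},
        {"run_id": "R1", "operator_id": "O1", "machine_id": "M1"},
    ]

    def test_provenance_labels_follow_design(self):
        cfg = small_cfg()
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        reps = simulate_replicates(truth, cfg, target, self.DESIGN)
        assert len(reps) == 3
        assert all(r.provenance["run_id"] == "R1" for r in reps)

    def test_replicates_differ_under_noise(self):
        cfg = small_cfg()
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        reps = simulate_replicates(truth, cfg, target, self.DESIGN)
        vafs = [tuple(v.vaf for v in r.variants) for r in reps]
        assert len(set(vafs)) > 1

    def test_zero_noise_replicates_identical(self):
        cfg = small_cfg(noise=0.0)
        target = simulate_target_space(cfg)
        truth = simulate_truth(cfg, target)
        reps = simulate_replicates(truth, cfg, target, self.DESIGN)
        assert reps[0].key_set() == reps[1].key_set() == reps[2].key_set()
        assert [v.vaf for v in reps[0].variants] == [v.vaf for v in reps[1].variants]


def test_cnv_calls_track_expected_copies():
    cfg = small_cfg(noise=0.0)
    calls = simulate_cnv_calls(list(cfg.cnv_panel), cfg)
    assert [(c.gene, c.copies) for c in calls] == list(cfg.cnv_panel)
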