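"""Domain types, coordinate conventions, normalization, and format I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelval import io as pio
from panelval.model import (
    CoverageProfile,
    FusionCall,
    GenomicInterval,
    SmallVariant,
    VariantCallSet,
    merge_intervals,
    normalize_variant,
)
from oracles import apply_variant_to_sequence, left_shift_indel


class TestGenomicInterval:
    def test_rejects_degenerate_intervals(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_vcf_bed_coordinate_conversion_exhaustive(self):
        """A 1-based position p lies in [s,e) iff s < p <= e — checked by
        enumerating every position against explicit base membership."""
        iv = GenomicInterval("chr1", 5, 9)  # covers 1-based positions 6..9
        member = {6, 7, 8, 9}
        for p in range(1, 15):
            assert iv.contains_pos1("chr1", p) == (p in member)
        assert not iv.contains_pos1("chr2", 7)


class TestSmallVariant:
    def test_class_inference_and_invariants(self):
        assert SmallVariant("chr1", 5, "A", "T").vclass == "SNV"
        assert SmallVariant("chr1", 5, "AT", "GC").vclass == "MNV"
        assert SmallVariant("chr1", 5, "ACG", "A").vclass == "deletion"
        assert SmallVariant("chr1", 5, "A", "ACG").vclass == "insertion"
        assert SmallVariant("chr1", 5, "AC", "TGA").vclass == "complex"
        with pytest.raises(ValueError):
            SmallVariant("chr1", 5, "A", "A")
        with pytest.raises(ValueError):
            SmallVariant("chr1", 5, "A", "T", depth=10, support=11)

    def test_duplicate_keys_rejected_in_call_set(self):
        v = SmallVariant("chr1", 5, "A", "T")
        with pytest.raises(ValueError, match="duplicate"):
            VariantCallSet("s", [v, v])


class TestNormalization:
    SEQ = "GGACAAAAGTTTCATCAG"  # 1-based coordinates

    def test_snv_unchanged(self):
        v = SmallVariant("chr1", 4, "C", "T")
        assert normalize_variant(v, self.SEQ).key == v.key

    def test_deletion_left_aligned_into_run(self):
        # delete two A's from the A-run at positions 5-8; right-anchored input
        v = SmallVariant("chr1", 6, "AAA", "A")
        n = normalize_variant(v, self.SEQ)
        assert (n.pos, n.ref, n.alt) == (4, "CAA", "C")

    def test_inconsistent_ref_rejected(self):
        with pytest.raises(ValueError, match="disagrees"):
            normalize_variant(SmallVariant("chr1", 4, "T", "G"), self.SEQ)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_indel_normalization_matches_rotation_oracle(self, data):
        rng_seq = data.draw(
            st.text(alphabet="ACGT", min_size=30, max_size=60), label="seq"
        )
        pos = data.draw(st.integers(10, len(rng_seq) - 8), label="pos")
        deletion = data.draw(st.booleans(), label="deletion")
        tail_len = data.draw(st.integers(1, 4), label="tail_len")
        anchor = rng_seq[pos - 1]
        if deletion:
            ref, alt = rng_seq[pos - 1 : pos + tail_len], anchor
        else:
            tail = data.draw(st.text(alphabet="ACGT", min_size=tail_len,
                                     max_size=tail_len), label="tail")
            ref, alt = anchor, anchor + tail
        if ref == alt:
            return
        v = SmallVariant("chr1", pos, ref, alt)
        n = normalize_variant(v, rng_seq)
        # oracle: repeated single-base left rotation
        exp_pos, exp_ref, exp_alt = left_shift_indel(rng_seq, pos, ref, alt)
        assert (n.pos, n.ref, n.alt) == (exp_pos, exp_ref, exp_alt)
        # idempotence and haplotype preservation
        n2 = normalize_variant(n, rng_seq)
        assert n2.key == n.key
        assert apply_variant_to_sequence(
            rng_seq, v.pos, v.ref, v.alt
        ) == apply_variant_to_sequence(rng_seq, n.pos, n.ref, n.alt)


class TestVcfIo:
    def _write(self, tmp_path, body, name="x.vcf"):
        header = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=10000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=VF,Number=A,Type=Float,Description="f">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
            '##FORMAT=<ID=SB,Number=1,Type=Float,Description="s">\n'
            '##FORMAT=<ID=AQ,Number=1,Type=Float,Description="a">\n'
            '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="o">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        p = tmp_path / name
        p.write_text(header + body)
        return p

    def test_single_biallelic_record(self, tmp_path):
        p = self._write(
            tmp_path,
            "chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP:VF:GQ:SB:AQ:AO\t"
            "0/1:500:0.25:60:0.1:20:125\n",
        )
        cs = pio.read_vcf(p)
        assert len(cs) == 1
        v = cs.variants[0]
        assert v.key == ("chr1", 100, "A", "T")
        assert v.depth == 500 and v.support == 125
        assert v.vaf == pytest.approx(0.25)

    def test_multiallelic_record_split_per_alt(self, tmp_path):
        """ALT 'A,T' yields two calls whose per-ALT fields are taken from the
        matching array slots (manual split of the record is the oracle)."""
        p = self._write(
            tmp_path,
            "chr1\t100\t.\tG\tA,T\t.\t.\t.\tGT:DP:VF:GQ:SB:AQ:AO\t"
            "0/1:600:0.2,0.05:60:0.1:20:120,30\n",
        )
        cs = pio.read_vcf(p)
        assert len(cs) == 2
        by_alt = {v.alt: v for v in cs.variants}
        assert by_alt["A"].support == 120 and by_alt["A"].vaf == pytest.approx(0.2)
        assert by_alt["T"].support == 30 and by_alt["T"].vaf == pytest.approx(0.05)
        assert by_alt["A"].depth == by_alt["T"].depth == 600

    def test_empty_body_is_empty_call_set(self, tmp_path):
        cs = pio.read_vcf(self._write(tmp_path, ""))
        assert len(cs) == 0

    def test_missing_tag_strict_vs_lenient(self, tmp_path):
        p = self._write(
            tmp_path, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP:VF\t0/1:500:0.25\n"
        )
        with pytest.raises(ValueError, match="missing mandatory tag"):
            pio.read_vcf(p, strict=True)
        cs = pio.read_vcf(p, strict=False)
        assert cs.variants[0].gq is None and cs.variants[0].depth == 500

    def test_round_trip_preserves_calls_and_provenance(self, tmp_path):
        cs = VariantCallSet(
            "S1",
            [
                SmallVariant("chr1", 100, "A", "T", vaf=0.25, depth=400,
                             support=100, gq=60, sb=0.1, aq=22.5),
                SmallVariant("chr1", 250, "GAA", "G", vaf=0.10, depth=380,
                             support=38, gq=50, sb=0.2, aq=18.0),
            ],
            provenance={"run_id": "R1", "operator_id": "O2"},
        )
        path = tmp_path / "rt.vcf"
        pio.write_vcf(cs, path)
        back = pio.read_vcf(path)
        assert back.sample_id == "S1"
        assert back.provenance == cs.provenance
        assert back.key_set() == cs.key_set()
        for a, b in zip(back.variants, cs.variants):
            assert a.depth == b.depth and a.support == b.support
            assert a.vaf == pytest.approx(b.vaf, abs=1e-6)  # float32 storage


class TestBed:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t99\t200\tTX1\t1\n")
        (iv,) = pio.read_target_bed(p)
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 99, 200)
        assert iv.transcript_id == "TX1" and iv.exon_index == 1

    def test_abutting_same_transcript_merged_and_sorted(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t200\t300\tTX1\t2\nchr1\t100\t200\tTX1\t1\n")
        merged = pio.read_target_bed(p)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 300)

    def test_different_transcripts_not_merged(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t200\tTX1\t1\nchr1\t200\t300\tTX2\t1\n")
        assert len(pio.read_target_bed(p)) == 2

    def test_invalid_interval_names_line(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t200\tTX1\n" "chr1\t300\t250\tTX1\n")
        with pytest.raises(ValueError, match="line 2"):
            pio.read_target_bed(p)


class TestTabularIo:
    def test_truth_json_round_trip(self, tmp_path, default_truth):
        path = tmp_path / "truth.json"
        pio.write_truth(default_truth, path)
        back = pio.read_truth(path)
        assert back.small_variant_keys() == default_truth.small_variant_keys()
        assert [v.vaf for v in back.small_variants] == [
            v.vaf for v in default_truth.small_variants
        ]
        assert back.fusions == default_truth.fusions
        assert back.cnvs == default_truth.cnvs

    def test_fusion_csv_round_trip_and_confidence(self, tmp_path):
        calls = [
            FusionCall("EML4", "ALK", 150, 620, "high", 42),
            FusionCall("MET", "MET", 300, 340, "low", 8, "splice_variant"),
        ]
        path = tmp_path / "f.csv"
        pio.write_fusion_csv(calls, path)
        back = pio.read_fusion_csv(path)
        assert back == calls
        assert back[0].confidence == "high"

    def test_cnv_csv_round_trip(self, tmp_path):
        calls = [pio.CnvCall("ERBB2", 9.25, "pass"), pio.CnvCall("MYC", 1.0, "fail")]
        path = tmp_path / "c.csv"
        pio.write_cnv_csv(calls, path)
        assert pio.read_cnv_csv(path) == calls

    def test_coverage_round_trip_and_gap_error(self, tmp_path):
        target = [GenomicInterval("chr1", 10, 20, transcript_id="TX1")]
        profile = CoverageProfile(target, np.arange(10) * 30)
        path = tmp_path / "d.tsv"
        pio.write_coverage_tsv(profile, path)
        back = pio.read_coverage_tsv(path, target=target)
        assert np.array_equal(back.depths, profile.depths)
        # punch a gap: strict read must fail, lenient fills zero
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:5] + lines[6:]) + "\n")
        with pytest.raises(ValueError, match="missing depth"):
            pio.read_coverage_tsv(path, target=target, strict=True)
        lenient = pio.read_coverage_tsv(path, target=target, strict=False)
        assert lenient.depths[5] == 0


class TestCoverageProfile:
    def test_depth_lookup_matches_iteration(self):
        ivs = [GenomicInterval("chr1", 0, 5), GenomicInterval("chr2", 10, 13)]
        prof = CoverageProfile(ivs, [1, 2, 3, 4, 5, 10, 11, 12])
        for chrom, pos, depth in prof.iter_positions():
            assert prof.depth_at(chrom, pos) == depth
        assert prof.depth_at("chr1", 6) is None
        assert prof.depth_at("chr3", 1) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="depth array"):
            CoverageProfile([GenomicInterval("chr1", 0, 5)], [1, 2, 3])


def test_merge_intervals_is_union_preserving():
    rng = np.random.default_rng(5)
    for _ in range(50):
        ivs = []
        for _ in range(rng.integers(1, 8)):
            s = int(rng.integers(0, 100))
            ivs.append(GenomicInterval("chr1", s, s + int(rng.integers(1, 30))))
        merged = merge_intervals(ivs)
        base_union = set()
        for iv in ivs:
            base_union.update(range(iv.start, iv.end))
        merged_union = set()
        for iv in merged:
            merged_union.update(range(iv.start, iv.end))
        assert merged_union == base_union
        assert all(a.end < b.start or a.chrom != b.chrom
                   for a, b in zip(merged, merged[1:]) or [])
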