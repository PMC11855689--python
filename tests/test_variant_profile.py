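"""Substitution classification, hard filtering, VAF, context windows."""

import math

import numpy as np
import pytest

from cbescan import io as cio
from cbescan import variant_profile as vp
from cbescan.errors import (
    InconsistentWindowError,
    InsufficientReplicatesError,
    InvalidSubstitutionError,
    MissingAnnotationError,
    UndefinedVafError,
    UnknownContigError,
)
from conftest import make_window

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestClassifySubstitution:
    def test_c_to_t_flags_deamination(self):
        assert vp.classify_substitution("C", "T") == ("C-to-T", True)
        assert vp.classify_substitution("G", "A") == ("G-to-A", True)

    def test_twelve_distinct_classes_and_flags(self):
        labels = set()
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                label, flag = vp.classify_substitution(ref, alt)
                labels.add(label)
                assert flag == ((ref, alt) in {("C", "T"), ("G", "A")})
        assert len(labels) == 12

    def test_complement_symmetry(self):
        # the class of a pair on the reverse strand is the complement pair's
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                rc_label, _ = vp.classify_substitution(COMP[ref], COMP[alt])
                assert rc_label == f"{COMP[ref]}-to-{COMP[alt]}"

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("N", "T"), ("C", "U")])
    def test_invalid_pairs_raise(self, ref, alt):
        with pytest.raises(InvalidSubstitutionError):
            vp.classify_substitution(ref, alt)


def _record(**overrides):
    nominal = dict(
        chrom="chr1", pos=100, ref_base="C", alt_base="T",
        qual=200.0, qd=10.0, sor=1.0, fs=5.0, mq=60.0,
        mq_rank_sum=0.0, read_pos_rank_sum=0.0,
    )
    nominal.update(overrides)
    return vp.SubstitutionRecord(**nominal)


class TestHardFilters:
    def test_single_violation_named(self):
        verdict = vp.apply_hard_filters(_record(sor=3.5))
        assert not verdict.passed
        assert verdict.failed_criteria == ("StrandOddsRatio",)

    def test_boundary_values_pass(self):
        # comparisons are strict: a value equal to its threshold passes
        rec = _record(qd=2.0, qual=30.0, sor=3.0, fs=60.0, mq=40.0,
                      mq_rank_sum=-12.5, read_pos_rank_sum=-8.0)
        assert vp.apply_hard_filters(rec).passed

    def test_multiple_violations_all_listed(self):
        verdict = vp.apply_hard_filters(_record(qd=1.9, qual=29.0))
        assert set(verdict.failed_criteria) == {"QualByDepth", "QUAL"}

    def test_missing_annotation_does_not_trigger(self):
        rec = _record(mq_rank_sum=None, read_pos_rank_sum=None)
        assert vp.apply_hard_filters(rec).passed

    def test_loosening_thresholds_is_monotone(self, rng):
        # a record passing under the defaults passes under any looser set
        defaults = vp.FilterThresholds()
        for _ in range(200):
            rec = _record(
                qd=rng.uniform(0, 5), qual=rng.uniform(0, 60),
                sor=rng.uniform(0, 5), fs=rng.uniform(0, 100),
                mq=rng.uniform(20, 70), mq_rank_sum=rng.uniform(-20, 5),
                read_pos_rank_sum=rng.uniform(-15, 5),
            )
            looser = vp.FilterThresholds(
                qd_min=defaults.qd_min - rng.uniform(0, 2),
                qual_min=defaults.qual_min - rng.uniform(0, 10),
                sor_max=defaults.sor_max + rng.uniform(0, 2),
                fs_max=defaults.fs_max + rng.uniform(0, 20),
                mq_min=defaults.mq_min - rng.uniform(0, 10),
                mq_rank_sum_min=defaults.mq_rank_sum_min - rng.uniform(0, 5),
                read_pos_rank_sum_min=defaults.read_pos_rank_sum_min
                - rng.uniform(0, 5),
            )
            if vp.apply_hard_filters(rec, defaults).passed:
                assert vp.apply_hard_filters(rec, looser).passed


class TestVaf:
    def test_direct_fraction(self):
        assert vp.compute_vaf(2, 8) == pytest.approx(0.8)
        assert vp.compute_vaf(10, 0) == 0.0

    def test_zero_depth_raises(self):
        with pytest.raises(UndefinedVafError):
            vp.compute_vaf(0, 0)

    def test_partition_boundary_goes_high(self):
        recs = [_record(pos=i, vaf=v) for i, v in
                enumerate([0.81, 0.8, 0.79], start=1)]
        high, low = vp.partition_by_vaf(recs)
        assert [r.vaf for r in high] == [0.81, 0.8]
        assert [r.vaf for r in low] == [0.79]

    def test_partition_exhaustive_and_disjoint(self, rng):
        recs = [_record(pos=i, vaf=float(v))
                for i, v in enumerate(rng.random(100), start=1)]
        high, low = vp.partition_by_vaf(recs, 0.5)
        assert len(high) + len(low) == len(recs)
        assert not (set(id(r) for r in high) & set(id(r) for r in low))

    def test_partition_edge_inputs(self):
        assert vp.partition_by_vaf([]) == ([], [])
        all_one = [_record(pos=i, vaf=1.0) for i in range(1, 4)]
        high, low = vp.partition_by_vaf(all_one)
        assert len(high) == 3 and low == []

    def test_partition_missing_vaf_raises(self):
        with pytest.raises(MissingAnnotationError):
            vp.partition_by_vaf([_record(vaf=None)])


class TestContextWindow:
    def test_exact_fit_full_contig(self, rng):
        contig = "".join(rng.choice(list("ACGT"), size=101))
        contig = contig[:50] + "C" + contig[51:]
        genome = {"c": contig}
        w = vp.extract_context_window(genome, "c", 51, 50, 50)
        assert w.sequence == contig
        assert w.site_offset == 50

    def test_g_center_is_reverse_complemented(self):
        genome = {"c": "AAGTT"}
        w = vp.extract_context_window(genome, "c", 3, 2, 2)
        # revcomp of AAGTT is AACTT; central base becomes C
        assert w.sequence == "AACTT"
        assert w.central_base == "C"
        assert w.origin == ("c", 3, "-")

    def test_asymmetric_g_center_geometry(self):
        #      pos: 123456
        genome = {"c": "TTTGAA"}
        w = vp.extract_context_window(genome, "c", 4, 2, 1)
        # oriented frame: revcomp strand around the C
        assert w.central_base == "C"
        assert w.upstream_len == 2 and w.downstream_len == 1
        assert w.sequence == "TTCA"  # revcomp("TGAA")

    def test_edge_padding(self):
        genome = {"c": "ACGTACGTACGTACGTACGT" * 2}
        w = vp.extract_context_window(genome, "c", 1, 20, 19,
                                      orient_to_c=False)
        assert w.sequence.startswith("N" * 20)
        assert len(w.sequence) == 40
        assert w.sequence[20:] == genome["c"][:20]

    def test_drop_padded(self):
        genome = {"c": "ACGT" * 30}
        assert vp.extract_context_window(genome, "c", 1, 20, 19,
                                         drop_padded=True) is None

    def test_unknown_contig(self):
        with pytest.raises(UnknownContigError):
            vp.extract_context_window({"c": "ACGT"}, "x", 1, 1, 1)

    def test_double_reverse_complement_is_identity(self):
        w = make_window("ACGTC", center=2)
        assert w.reverse_complement().reverse_complement() == w


class TestNeighborFrequencies:
    def test_all_w_neighbors(self):
        _, w5, w3 = vp.neighbor_frequencies(
            [make_window("ACA"), make_window("TCT")])
        assert w5 == 1.0 and w3 == 1.0

    def test_no_w_neighbors(self):
        _, w5, w3 = vp.neighbor_frequencies(
            [make_window("GCG"), make_window("GCG")])
        assert w5 == 0.0 and w3 == 0.0

    def test_mixed_lengths_raise(self):
        with pytest.raises(InconsistentWindowError):
            vp.neighbor_frequencies([make_window("ACA"), make_window("AACAA")])

    def test_column_sums_equal_window_count(self, rng):
        windows = [
            make_window("".join(rng.choice(list("ACGT"), 2)) + "C"
                        + "".join(rng.choice(list("ACGT"), 2)))
            for _ in range(50)
        ]
        matrix, _, _ = vp.neighbor_frequencies(windows)
        assert (matrix.counts.sum(axis=0) == 50).all()

    def test_spiked_w_probability_recovered(self):
        # plant 5'-W with probability 0.7; the observed fraction must lie
        # within the 99% binomial bound of the planted rate
        gen = np.random.default_rng(7)
        n = 1000
        windows = []
        for _ in range(n):
            five = gen.choice(list("AT")) if gen.random() < 0.7 \
                else gen.choice(list("CG"))
            three = gen.choice(list("ACGT"))
            windows.append(make_window(five + "C" + three))
        _, w5, _ = vp.neighbor_frequencies(windows)
        bound = 2.576 * math.sqrt(0.7 * 0.3 / n)
        assert abs(w5 - 0.7) < bound


class TestWEnrichment:
    def test_identical_groups(self):
        t, p = vp.compare_w_enrichment([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert t == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        t, p = vp.compare_w_enrichment([0.7, 0.72, 0.71], [0.5, 0.52, 0.51])
        assert p < 0.05 and t > 0

    def test_matches_closed_form_welch(self):
        a, b = [0.7, 0.72, 0.71], [0.5, 0.52, 0.51]
        t, _ = vp.compare_w_enrichment(a, b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        expected = (np.mean(a) - np.mean(b)) / math.sqrt(va / 3 + vb / 3)
        assert t == pytest.approx(expected, abs=1e-9)

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            vp.compare_w_enrichment([0.5], [0.5, 0.6])


class TestSpectrumAndVcf:
    def test_spectrum_counts_and_fractions(self):
        recs = [_record(), _record(), _record(ref_base="G", alt_base="A")]
        spec = vp.substitution_spectrum(recs).set_index("class")
        assert spec.loc["C-to-T", "count"] == 2
        assert spec.loc["G-to-A", "fraction"] == pytest.approx(1 / 3)
        assert len(spec) == 12
        assert spec["count"].sum() == 3

    def test_vcf_reader_decomposes_multiallelic(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##INFO=<ID=QD,Number=1,Type=Float,Description="d">\n'
            '##INFO=<ID=SOR,Number=1,Type=Float,Description="d">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="d">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t10\t.\tC\tT,G\t100\t.\tQD=12.5;SOR=1.1\tGT:AD\t1/2:4,10,6\n"
            "chr1\t20\t.\tA\tAT\t50\t.\tQD=8\tGT:AD\t0/1:5,5\n"
        )
        recs = vp.read_vcf_substitutions(str(path))
        assert len(recs) == 2  # indel skipped, two alt alleles decomposed
        assert (recs[0].alt_base, recs[1].alt_base) == ("T", "G")
        assert recs[0].vaf == pytest.approx(10 / 14)
        assert recs[1].vaf == pytest.approx(6 / 10)
        assert recs[0].qd == pytest.approx(12.5, abs=1e-5)

    def test_writer_reader_round_trip(self, tmp_path):
        rows = [{
            "chrom": "chr1", "pos": 42, "ref": "C", "alt": "T", "qual": 99.0,
            "info": {"QD": 11.25, "SOR": 0.75, "FS": 3.0, "MQ": 60.0,
                     "MQRankSum": -1.5, "ReadPosRankSum": 0.5},
            "ad": (6, 18),
        }]
        path = tmp_path / "w.vcf"
        cio.write_vcf(rows, {"chr1": 1000}, path, sample_name="s")
        (rec,) = vp.read_vcf_substitutions(str(path))
        assert (rec.chrom, rec.pos, rec.ref_base, rec.alt_base) == \
            ("chr1", 42, "C", "T")
        assert rec.vaf == pytest.approx(0.75)
        assert rec.sor == pytest.approx(0.75, abs=1e-6)
        assert rec.mq_rank_sum == pytest.approx(-1.5, abs=1e-6)


def test_intersect_positions_keeps_common_calls():
    a = [_record(pos=1), _record(pos=2), _record(pos=3)]
    b = [_record(pos=2), _record(pos=3)]
    c = [_record(pos=3), _record(pos=9)]
    common = vp.intersect_positions(a, b, c)
    assert [r.pos for r in common] == [3]
    assert vp.intersect_positions() == []
    assert [r.pos for r in vp.intersect_positions(a)] == [1, 2, 3]
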