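"""CDS assembly, premature-stop scanning, genome mapping, ESD."""

import numpy as np
import pytest

from cbescan import classifiers as cl
from cbescan import prs_scan as ps
from cbescan._seq import STOP_CODONS, revcomp
from cbescan.errors import CoordinateError, FrameError

SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in STOP_CODONS]


def model(intervals, strand="+", chrom="c", tid="t1"):
    return ps.TranscriptModel(transcript_id=tid, chrom=chrom, strand=strand,
                              cds_intervals=intervals)


def random_cds(rng, n_codons):
    codons = ["ATG"]
    codons += [SENSE[rng.integers(len(SENSE))] for _ in range(n_codons - 2)]
    codons.append(sorted(STOP_CODONS)[rng.integers(3)])
    return "".join(codons)


class TestAssembleCds:
    def test_single_plus_interval(self):
        genome = {"c": "ATGAAATAA"}
        cds = ps.assemble_cds(model([(0, 9)]), genome)
        assert cds.sequence == "ATGAAATAA"
        assert cds.aa_length == 2
        assert cds.is_valid_orf

    def test_minus_strand_hand_check(self):
        orf = "ATGCAATAA"
        genome = {"c": "GG" + revcomp(orf) + "CC"}
        cds = ps.assemble_cds(model([(2, 11)], strand="-"), genome)
        assert cds.sequence == orf
        assert cds.is_valid_orf

    def test_two_exon_splice_equals_hand_splice(self):
        orf = "ATGAAACCCGGGTTTACGTAATAA"  # hand-spliced reference
        exon1, exon2 = orf[:10], orf[10:]
        genome = {"c": "TT" + exon1 + "GTAAGT" + exon2 + "AA"}
        m = model([(2, 12), (18, 18 + len(exon2))])
        cds = ps.assemble_cds(m, genome)
        assert cds.sequence == orf

    def test_invalid_orf_flags_not_errors(self):
        genome = {"c": "CCCTAACCC"}
        cds = ps.assemble_cds(model([(0, 9)]), genome)
        assert not cds.starts_with_atg
        assert not cds.internal_stop_free or not cds.ends_with_stop

    def test_interval_outside_contig(self):
        with pytest.raises(CoordinateError):
            ps.assemble_cds(model([(0, 99)]), {"c": "ACGT"})


def offsets(records):
    return [r.cds_offset for r in records]


class TestFindPrs:
    def test_all_three_stop_forming_codons(self):
        cds = ps.CodingSequence("t", "ATGCAACAGCGATAA", ends_with_stop=True)
        recs = ps.find_prs(cds)
        assert [r.codon_index for r in recs] == [1, 2, 3]
        assert [r.codon for r in recs] == ["CAA", "CAG", "CGA"]
        assert offsets(recs) == [3, 6, 9]

    def test_no_prs_without_stop_forming_codons(self):
        assert ps.find_prs(ps.CodingSequence("t", "ATGGGGTAA",
                                             ends_with_stop=True)) == []

    def test_c_at_other_codon_positions_is_not_prs(self):
        # TCA and TGC contain C but no single C->T makes a stop
        cds = ps.CodingSequence("t", "ATGTCATGCTAA", ends_with_stop=True)
        assert ps.find_prs(cds) == []
        assert ps.brute_force_prs(cds) == []

    def test_terminal_stop_excluded(self):
        # CAA as the last sense codon counts; the TAA terminator does not
        cds = ps.CodingSequence("t", "ATGCAATAA", ends_with_stop=True)
        assert offsets(ps.find_prs(cds)) == [3]

    def test_repeated_motif(self):
        cds = ps.CodingSequence("t", "CAACAACAATAA", ends_with_stop=True)
        assert offsets(ps.find_prs(cds)) == [0, 3, 6]
        assert ps.brute_force_prs(cds) == [0, 3, 6]

    def test_frame_error_and_tolerate(self):
        cds = ps.CodingSequence("t", "ATGCAAT")
        with pytest.raises(FrameError):
            ps.find_prs(cds)
        assert offsets(ps.find_prs(cds, tolerate_frame=True)) == [3]

    def test_oracle_agreement_on_random_cds(self):
        gen = np.random.default_rng(5)
        for _ in range(300):
            seq = random_cds(gen, int(gen.integers(5, 60)))
            cds = ps.CodingSequence("t", seq, ends_with_stop=True)
            assert offsets(ps.find_prs(cds)) == ps.brute_force_prs(cds)

    def test_oracle_hits_only_codon_position_one(self):
        gen = np.random.default_rng(6)
        for _ in range(100):
            seq = random_cds(gen, int(gen.integers(5, 40)))
            cds = ps.CodingSequence("t", seq, ends_with_stop=True)
            assert all(o % 3 == 0 for o in ps.brute_force_prs(cds))


class TestMapToGenome:
    def test_single_exon_plus(self):
        m = model([(100, 130)])
        chrom, pos, strand = ps.map_to_genome(m, 5)
        assert (chrom, pos - 1, strand) == ("c", 105, "+")

    def test_two_exon_boundary(self):
        m = model([(10, 20), (50, 60)])
        assert ps.map_to_genome(m, 9)[1] - 1 == 19   # last base of exon 1
        assert ps.map_to_genome(m, 10)[1] - 1 == 50  # first base of exon 2

    def test_out_of_range(self):
        with pytest.raises(CoordinateError):
            ps.map_to_genome(model([(0, 9)]), 9)

    def test_round_trip_with_assemble(self, study):
        # every CDS base equals the strand-adjusted genome base at its
        # mapped coordinate, for random multi-exon models on both strands
        for m in study.transcripts[:20]:
            cds = ps.assemble_cds(m, study.genome)
            idx = np.linspace(0, len(cds.sequence) - 1, 15).astype(int)
            for off in idx:
                chrom, pos, strand = ps.map_to_genome(m, int(off))
                base = study.genome[chrom][pos - 1]
                if strand == "-":
                    base = revcomp(base)
                assert base == cds.sequence[off]


class TestPrsContext:
    def test_single_exon_modes_agree(self):
        orf = "ATG" + "CAA" + "GGG" * 20 + "TAA"
        genome = {"c": "A" * 30 + orf + "T" * 30}
        m = model([(30, 30 + len(orf))])
        cds = ps.assemble_cds(m, genome)
        (prs,) = ps.find_prs(cds)
        prs.chrom, prs.genomic_pos, prs.strand = ps.map_to_genome(m, prs.cds_offset)
        g = ps.prs_context(genome, m, prs, mode="genomic")
        s = ps.prs_context(genome, m, prs, mode="spliced")
        assert g.central_base == s.central_base == "C"
        # spliced context pads with N before the CDS start; genomic reads
        # the flanking genome, so only the in-CDS parts must agree
        assert g.sequence[20 - 3:] [:6] == s.sequence[20 - 3:][:6]

    def test_intron_proximal_modes_differ_past_junction(self):
        exon1 = "ATGCAA"          # PRS at offset 3, 3 bases before the junction
        exon2 = "GGGTTTACATAA"
        intron = "GTAAGTAAGT"
        genome = {"c": exon1 + intron + exon2}
        m = model([(0, 6), (16, 28)])
        cds = ps.assemble_cds(m, genome)
        (prs,) = ps.find_prs(cds)
        g = ps.prs_context(genome, m, prs, upstream=3, downstream=6, mode="genomic")
        s = ps.prs_context(genome, m, prs, upstream=3, downstream=6, mode="spliced")
        assert g.sequence[:6] == s.sequence[:6]      # up to the junction
        assert g.sequence[6:] != s.sequence[6:]      # intron vs next exon
        assert g.sequence[6:] == intron[:4]          # intron bases follow

    def test_minus_strand_window_is_revcomp_of_plus_slice(self):
        orf = "ATGCAAGGGTAA"
        genome = {"c": "ACGTACGTAC" + revcomp(orf) + "GGGGGGGGGG"}
        m = model([(10, 22)], strand="-")
        cds = ps.assemble_cds(m, genome)
        (prs,) = ps.find_prs(cds)
        prs_chrom, pos, strand = ps.map_to_genome(m, prs.cds_offset)
        w = ps.prs_context(genome, m, prs, upstream=4, downstream=4)
        plus_slice = genome["c"][pos - 1 - 4:pos - 1 + 5]
        assert w.sequence == revcomp(plus_slice)
        assert w.central_base == "C"


class TestEffectiveAndEsd:
    def test_nnn_makes_all_effective(self, study):
        m = study.transcripts[0]
        recs, esds = ps.scan_transcript(
            study.genome, m, [cl.get_classifier("nnn")])
        assert all(r.effective for r in recs)
        assert esds[0].n_effective == esds[0].n_prs

    def test_effective_count_nesting(self, study):
        for m in study.transcripts[:10]:
            _, esds = ps.scan_transcript(
                study.genome, m,
                [cl.get_classifier(n) for n in ("acw", "wcw", "nnn")])
            by = {e.classifier: e for e in esds}
            assert by["ACW"].n_effective <= by["WCW"].n_effective \
                <= by["NNN"].n_effective
            assert by["ACW"].esd <= by["WCW"].esd <= by["NNN"].esd

    def test_esd_values(self):
        assert ps.compute_esd(2, 10, 100) == pytest.approx(0.002)
        assert ps.compute_esd(0, 5, 10) == 0.0
        assert ps.compute_esd(0, 0, 10) == 0.0
        assert ps.compute_esd(5, 5, 50) == pytest.approx(0.02)  # = 1/aa_length

    def test_esd_bounds_and_errors(self):
        with pytest.raises(ValueError):
            ps.compute_esd(6, 5, 50)
        with pytest.raises(ValueError):
            ps.compute_esd(1, 1, 0)
        # 0 <= ESD <= 1/aa_length, monotone in n_effective
        prev = -1.0
        for k in range(6):
            esd = ps.compute_esd(k, 5, 40)
            assert 0 <= esd <= 1 / 40 + 1e-12
            assert esd >= prev
            prev = esd

    def test_additive_normalization_variant(self):
        assert ps.compute_esd(2, 10, 100, normalization="additive") == \
            pytest.approx(2 / 110)
        with pytest.raises(ValueError):
            ps.compute_esd(1, 2, 3, normalization="bogus")
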