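"""Coordinate types, FASTA/GFF3 round trips, intron extraction, exonic overlap."""

import numpy as np
import pytest

from flanno.core import Exon, GenomeSequence, Transcript, exonic_overlap, introns_of
from flanno.io import read_fasta, read_gff3, write_fasta, write_gff3

from conftest import T, make_annotation, random_exon_chain, exonic_bases


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nACGT\n")
        g = read_fasta(p)
        assert list(g) == ["chr1"] and len(g["chr1"]) == 4

    def test_two_records_order_preserved(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nAC\n>s2\nGGTT\n")
        assert list(read_fasta(p)) == ["s1", "s2"]

    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nacgt\n")
        assert read_fasta(p)["x"].sequence == "ACGT"

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\n>y\nAC\n")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_roundtrip(self, tmp_path):
        genome = {"c1": GenomeSequence("c1", "ACGTACGT" * 30)}
        p = tmp_path / "g.fa"
        write_fasta(genome, p)
        assert read_fasta(p)["c1"].sequence == genome["c1"].sequence

    def test_fetch_bounds(self):
        g = GenomeSequence("c", "ACGT")
        assert g.fetch(1, 3) == "CG"
        with pytest.raises(IndexError):
            g.fetch(2, 5)
        with pytest.raises(IndexError):
            g.fetch(-1, 2)


GFF = """##gff-version 3
chr1\tsrc\tgene\t1\t200\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t1\t200\t.\t+\t.\tID=tA1;Parent=geneA
chr1\tsrc\texon\t11\t20\t.\t+\t.\tID=tA1.e1;Parent=tA1
chr1\tsrc\texon\t51\t90\t.\t+\t.\tID=tA1.e2;Parent=tA1
chr1\tsrc\texon\t151\t200\t.\t+\t.\tID=tA1.e3;Parent=tA1
chr1\tsrc\tCDS\t55\t90\t.\t+\t0\tID=tA1.c1;Parent=tA1
chr1\tsrc\tCDS\t151\t180\t.\t+\t0\tID=tA1.c2;Parent=tA1
chr1\tsrc\tmRNA\t1\t90\t.\t+\t.\tID=tA2;Parent=geneA
chr1\tsrc\texon\t11\t90\t.\t+\t.\tID=tA2.e1;Parent=tA2
"""


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        ann = read_gff3(p)
        # GFF3 exon 11..20 (1-based inclusive) -> internal (10, 20)
        assert ann.transcripts["tA1"].exons[0] == Exon(10, 20)

    def test_exon_chain_and_gene_map(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        ann = read_gff3(p)
        assert ann.transcripts["tA1"].n_exons == 3
        assert ann.gene_of == {"tA1": "geneA", "tA2": "geneA"}
        assert ann.cds_span["tA1"] == (54, 180)

    def test_orphan_mrna_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tmRNA\t1\t50\t.\t+\t.\tID=t1\n"
            "chr1\ts\texon\t1\t50\t.\t+\t.\tID=e1;Parent=t1\n"
        )
        with pytest.raises(ValueError):
            read_gff3(p)

    def test_roundtrip_bit_exact(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        ann = read_gff3(p)
        q = tmp_path / "b.gff3"
        write_gff3(ann, q)
        back = read_gff3(q)
        assert {t: back.transcripts[t].exons for t in back.transcripts} == {
            t: ann.transcripts[t].exons for t in ann.transcripts
        }
        assert back.gene_of == ann.gene_of
        assert back.cds_span == ann.cds_span


class TestTranscriptInvariants:
    @pytest.mark.parametrize(
        "exons",
        [[(10, 10)], [(10, 5)], [(0, 10), (5, 20)], [(0, 10), (10, 20)], []],
    )
    def test_invalid_exon_chains_rejected(self, exons):
        with pytest.raises(ValueError):
            T("bad", exons)

    def test_three_prime_end_by_strand(self):
        t = T("t", [(0, 10), (20, 30)])
        assert t.three_prime_end() == 29
        assert T("t", [(0, 10), (20, 30)], strand="-").three_prime_end() == 0


class TestIntrons:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(0, 10), (20, 30)], [(10, 20)]),
            ([(0, 5)], []),
            ([(0, 5), (10, 15), (20, 25)], [(5, 10), (15, 20)]),
        ],
    )
    def test_examples(self, exons, expected):
        t = T("t", exons)
        assert [(j.start, j.end) for j in introns_of(t)] == expected

    def test_intron_lengths_complement_exonic_length(self, rng):
        for _ in range(50):
            t = Transcript("t", "c", "+", random_exon_chain(rng))
            intron_bp = sum(j.end - j.start for j in introns_of(t))
            assert intron_bp == t.span - t.exonic_length


class TestExonicOverlap:
    def test_identity(self):
        a = T("a", [(0, 50), (100, 150)])
        rep = exonic_overlap(a, a)
        assert rep.frac_a == rep.frac_b == 1.0 and rep.max_single_exon_frac == 1.0

    def test_disjoint(self):
        rep = exonic_overlap(T("a", [(0, 50)]), T("b", [(60, 100)]))
        assert rep == (0, 0.0, 0.0, 0.0)

    def test_ten_percent_example(self):
        rep = exonic_overlap(T("a", [(0, 100)]), T("b", [(90, 190)]))
        assert rep.shared_bp == 10
        assert rep.frac_a == pytest.approx(0.10)
        assert rep.frac_b == pytest.approx(0.10)

    def test_different_chrom_all_zero(self):
        rep = exonic_overlap(T("a", [(0, 100)]), T("b", [(0, 100)], chrom="chr2"))
        assert rep.shared_bp == 0

    def test_matches_per_base_oracle_and_symmetry(self, rng):
        """shared_bp equals the per-base set-intersection oracle; symmetric."""
        for _ in range(300):
            a = Transcript("a", "c", "+", random_exon_chain(rng, hi=800))
            b = Transcript("b", "c", "+", random_exon_chain(rng, hi=800))
            rep = exonic_overlap(a, b)
            swapped = exonic_overlap(b, a)
            assert rep.shared_bp == len(exonic_bases(a) & exonic_bases(b))
            assert swapped.shared_bp == rep.shared_bp
            assert (swapped.frac_a, swapped.frac_b) == (rep.frac_b, rep.frac_a)
            assert swapped.max_single_exon_frac == rep.max_single_exon_frac
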