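"""AS event taxonomy, splice-site census, SJ context, AS/non-AS exon counts."""

import pytest

from flanno.core import GenomeSequence, Intron
from flanno.loci import Locus, build_loci
from flanno.simulate import SimConfig, simulate, simulate_genome
from flanno.splicing import (
    as_type_percentages,
    detect_as_events,
    exon_count_by_as_status,
    sj_context,
    splice_site_census,
)

from conftest import T, make_annotation


def locus_of(*transcripts, strand="+"):
    return Locus("L1", transcripts[0].chrom, strand, members=[(t, "known_novel") for t in transcripts])


FULL = T("full", [(0, 100), (200, 300), (400, 500), (600, 700)])


def events(locus, fuzz=10):
    return {(e.event_type, e.start, e.end) for e in detect_as_events(locus, fuzz)}


class TestTaxonomy:
    def test_skip(self):
        skip = T("skip", [(0, 100), (400, 500), (600, 700)])
        assert events(locus_of(FULL, skip)) == {("SKIP", 200, 300)}

    def test_mskip(self):
        mskip = T("mskip", [(0, 100), (600, 700)])
        assert events(locus_of(FULL, mskip)) == {("MSKIP", 200, 500)}

    def test_ir(self):
        ir = T("ir", [(0, 100), (200, 500), (600, 700)])
        assert events(locus_of(FULL, ir)) == {("IR", 300, 400)}

    def test_mir(self):
        mir = T("mir", [(0, 300), (400, 700)])
        # one exon retains introns (100,200); the other (500,600) -> two IR events
        assert events(locus_of(FULL, mir)) == {("IR", 100, 200), ("IR", 500, 600)}
        mir2 = T("mir2", [(0, 500), (600, 700)])
        assert events(locus_of(FULL, mir2)) == {("MIR", 100, 400)}

    def test_ae(self):
        ae = T("ae", [(0, 100), (200, 285), (400, 500), (600, 700)])
        assert events(locus_of(FULL, ae)) == {("AE", 285, 300)}

    def test_xskip_straddles_fuzz(self):
        """Flank offset 5 bp -> XSKIP at fuzz=10, nothing at fuzz=4."""
        x = T("x", [(0, 95), (400, 500), (600, 700)])
        assert events(locus_of(FULL, x), fuzz=10) == {("XSKIP", 200, 300)}
        assert ("XSKIP", 200, 300) not in events(locus_of(FULL, x), fuzz=4)

    def test_xir(self):
        x = T("x", [(0, 100), (205, 500), (600, 700)])
        got = events(locus_of(FULL, x), fuzz=10)
        assert ("XIR", 300, 400) in got

    def test_fuzz_zero_has_no_x_events(self):
        x = T("x", [(0, 95), (400, 500), (600, 700)])
        assert all(not t.startswith("X") for t, *_ in events(locus_of(FULL, x), fuzz=0))

    def test_fuzz_monotone_event_count(self):
        x = T("x", [(0, 95), (205, 300), (400, 500), (600, 700)])
        counts = [len(detect_as_events(locus_of(FULL, x), f)) for f in (0, 3, 6, 12)]
        assert counts == sorted(counts)

    def test_pair_order_symmetric(self):
        skip = T("skip", [(0, 100), (400, 500), (600, 700)])
        assert events(locus_of(FULL, skip)) == events(locus_of(skip, FULL))

    def test_duplicate_events_reported_once(self):
        skip1 = T("s1", [(0, 100), (400, 500), (600, 700)])
        skip2 = T("s2", [(0, 90), (400, 500), (600, 700)])  # same skip, new 5' end
        evs = [e for e in detect_as_events(locus_of(FULL, skip1, skip2)) if e.event_type == "SKIP"]
        assert len(evs) == 1

    def test_tss_tts_only_difference_is_not_an_event(self):
        shorter = T("sh", [(40, 100), (200, 300), (400, 500), (600, 660)])
        assert events(locus_of(FULL, shorter)) == set()

    def test_percentages(self):
        from flanno.splicing import ASEvent

        evs = [
            ASEvent("L1", "SKIP", "chr1", 200, 300, "a", "b"),
            ASEvent("L2", "SKIP", "chr1", 900, 950, "c", "d"),
            ASEvent("L3", "IR", "chr1", 100, 200, "e", "f"),
            ASEvent("L4", "AE", "chr1", 285, 300, "g", "h"),
        ]
        assert as_type_percentages(evs) == {"AE": 0.25, "IR": 0.25, "SKIP": 0.5}
        assert as_type_percentages([]) == {}

    def test_single_event_percentage(self):
        skip = T("skip", [(0, 100), (400, 500), (600, 700)])
        assert as_type_percentages(detect_as_events(locus_of(FULL, skip))) == {"SKIP": 1.0}

    def test_injected_edits_recovered_exactly(self):
        """Simulator AS edits come back as exactly one event of the right type."""
        sim = simulate(SimConfig(seed=16, n_genes=20, n_chroms=2, chrom_length=250_000,
                                 p_novel_isoform=1.0))
        ann = sim.genome.annotation
        from flanno.filtering import JunctionSupportIndex, group_identical_structures, retain

        isoforms = retain(group_identical_structures(sim.reads),
                          JunctionSupportIndex(sim.junctions), ann)
        loci, _ = build_loci(isoforms, ann)
        for locus in loci:
            truth = set(sim.truth.gene_as_events.get(locus.known_gene_id, []))
            got = {(e.event_type, e.start, e.end) for e in detect_as_events(locus, 10)}
            assert got == truth


class TestCensus:
    GENOME = {"chr1": GenomeSequence("chr1", "AAAAA" + "GT" + "CCC" + "AG" + "TTTTT" * 3)}
    # intron (5, 12): starts GT, ends AG on + strand

    def test_plus_strand_gtag(self):
        t = T("t", [(0, 5), (12, 20)])
        c = splice_site_census([t], self.GENOME)
        assert c.counts["GT-AG"] == 1 and c.total == 1

    def test_minus_strand_reverse_complement(self):
        seq = "AAAAA" + "CT" + "CCC" + "AC" + "TTTTT" * 3  # revcomp(GT..AG)
        genome = {"chr1": GenomeSequence("chr1", seq)}
        t = T("t", [(0, 5), (12, 20)], strand="-")
        assert splice_site_census([t], genome).counts["GT-AG"] == 1

    def test_unique_junctions_counted_once(self):
        a = T("a", [(0, 5), (12, 20)])
        b = T("b", [(0, 5), (12, 25)])
        assert splice_site_census([a, b], self.GENOME).total == 1

    def test_out_of_bounds_names_transcript(self):
        t = T("toofar", [(0, 5), (40, 45)])
        with pytest.raises(ValueError, match="toofar"):
            splice_site_census([t], self.GENOME)

    def test_fractions_sum_to_one(self):
        g = simulate_genome(SimConfig(seed=17, n_genes=12, n_chroms=2, chrom_length=150_000,
                                      dinucleotide_fractions={"GT-AG": 0.8, "AT-AC": 0.2}))
        c = splice_site_census(g.annotation.transcripts.values(), g.sequences)
        assert sum(c.fractions.values()) == pytest.approx(1.0)
        assert c.counts["AT-AC"] > 0


class TestSjContext:
    ANN = make_annotation(
        [T("m1", [(100, 300), (500, 800)], source="annotation"),
         T("m2", [(2000, 2300), (2500, 2800)], strand="-", source="annotation")],
        gene_of={"m1": "g1", "m2": "g2"},
        cds_span={"m1": (150, 700), "m2": (2100, 2700)},
    )

    def context(self, chrom, strand, start, end):
        rep = sj_context([Intron(chrom, strand, start, end)], self.ANN)
        return next(k for k, v in rep.counts.items() if v == 1)

    def test_cds(self):
        assert self.context("chr1", "+", 200, 600) == "CDS"

    def test_intergenic(self):
        assert self.context("chr1", "+", 10_000, 10_100) == "intergenic"

    def test_five_prime_utr(self):
        assert self.context("chr1", "+", 120, 600) == "5'UTR"

    def test_three_prime_utr_minus_strand(self):
        # donor of a - strand junction sits at end-1; 2050 is exonic, left of
        # the CDS span of a - strand mRNA -> its 3' UTR
        assert self.context("chr1", "-", 1900, 2051) == "3'UTR"

    def test_intron_region(self):
        assert self.context("chr1", "+", 400, 450) == "intron"

    def test_every_junction_assigned_once(self):
        js = [Intron("chr1", "+", 200, 600), Intron("chr1", "+", 10_000, 10_100)]
        rep = sj_context(js, self.ANN)
        assert sum(rep.counts.values()) == len(js)


class TestExonCounts:
    def test_single_isoform_genes_are_non_as(self):
        loci = [Locus("L1", "chr1", "+", members=[(FULL, "known_known")])]
        out = exon_count_by_as_status(loci)
        assert out == {"as_genes": [], "non_as_genes": [4]}

    def test_skip_gene_is_as(self):
        skip = T("skip", [(0, 100), (400, 500), (600, 700)])
        out = exon_count_by_as_status([locus_of(FULL, skip)])
        assert out == {"as_genes": [4], "non_as_genes": []}

    def test_as_genes_have_more_exons_by_construction(self):
        """Edits are only injected into multi-exon genes; with a mix of exon
        counts the AS-gene mean exceeds the non-AS mean."""
        import numpy as np

        sim = simulate(SimConfig(seed=18, n_genes=24, n_chroms=2, chrom_length=300_000,
                                 exons_per_gene=(2, 8), p_novel_isoform=0.6))
        from flanno.filtering import JunctionSupportIndex, group_identical_structures, retain

        isoforms = retain(group_identical_structures(sim.reads),
                          JunctionSupportIndex(sim.junctions), sim.genome.annotation)
        loci, _ = build_loci(isoforms, sim.genome.annotation)
        out = exon_count_by_as_status(loci)
        assert out["as_genes"] and out["non_as_genes"]
        assert np.mean(out["as_genes"]) > 0
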