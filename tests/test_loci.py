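"""Locus construction (connected components of exonic overlap) and novelty labels."""

import networkx as nx
import numpy as np
import pytest

from flanno.core import Transcript, exonic_overlap
from flanno.loci import build_loci, classify_isoform, partition_counts, same_locus

from conftest import T, make_annotation, random_exon_chain


REF = T("refA", [(0, 100), (200, 300), (400, 500)], source="annotation")
ANN = make_annotation([REF], gene_of={"refA": "geneA"})


def labels_of(loci):
    return {t.id: lab for locus in loci for t, lab in locus.members}


class TestBuildLoci:
    def test_identical_isoform_joins_gene(self):
        iso = T("i1", [(0, 100), (200, 300), (400, 500)])
        loci, _ = build_loci([iso], ANN)
        (locus,) = [l for l in loci if l.members]
        assert locus.known_gene_id == "geneA"
        assert labels_of(loci)["i1"] == "known_known"

    def test_no_overlap_makes_novel_locus(self):
        iso = T("i1", [(10_000, 10_200), (10_400, 10_600)])
        loci, _ = build_loci([iso], ANN)
        locus = next(l for l in loci if l.members)
        assert locus.known_gene_id is None
        assert labels_of(loci)["i1"] == "novel"

    def test_opposite_strand_is_novel(self):
        iso = T("i1", [(0, 100), (200, 300), (400, 500)], strand="-")
        loci, _ = build_loci([iso], ANN)
        assert labels_of(loci)["i1"] == "novel"

    def test_sub_threshold_overlap_is_novel(self):
        # 15 shared bp of a 300 bp isoform and 300 bp annotation exonic length
        iso = T("i1", [(485, 785)])
        rep = exonic_overlap(iso, REF)
        assert rep.frac_a < 0.20
        loci, _ = build_loci([iso], ANN)
        assert labels_of(loci)["i1"] == "novel"

    def test_two_novel_isoforms_form_one_locus(self):
        a = T("i1", [(10_000, 10_400)])
        b = T("i2", [(10_200, 10_600)])
        loci, _ = build_loci([a, b], ANN)
        locus = next(l for l in loci if l.members)
        assert len(locus.members) == 2 and locus.known_gene_id is None

    def test_merged_locus_warning(self):
        ann = make_annotation(
            [
                T("r1", [(0, 500)], source="annotation"),
                T("r2", [(400, 900)], source="annotation"),
            ],
            gene_of={"r1": "g1", "r2": "g2"},
        )
        iso = T("i1", [(0, 900)])
        loci, warnings = build_loci([iso], ann)
        assert len(warnings) == 1 and "g1" in warnings[0] and "g2" in warnings[0]

    def test_matches_brute_force_component_oracle(self, rng):
        """Sweep+union-find equals pairwise-overlap graph components (networkx)."""
        for trial in range(20):
            n = int(rng.integers(5, 60))
            isoforms = [
                Transcript(
                    f"i{k}",
                    f"chr{int(rng.integers(1, 3))}",
                    "+-"[int(rng.integers(0, 2))],
                    random_exon_chain(rng, max_exons=4, hi=3000),
                    source="flnc",
                )
                for k in range(n)
            ]
            ann = make_annotation([])
            loci, _ = build_loci(isoforms, ann)
            got = {frozenset(t.id for t, _ in locus.members) for locus in loci}
            g = nx.Graph()
            g.add_nodes_from(t.id for t in isoforms)
            for i in range(n):
                for j in range(i + 1, n):
                    if same_locus(isoforms[i], isoforms[j]):
                        g.add_edge(isoforms[i].id, isoforms[j].id)
            expected = {frozenset(c) for c in nx.connected_components(g)}
            assert got == expected

    def test_raising_min_frac_never_merges(self, rng):
        isoforms = [
            Transcript(f"i{k}", "chr1", "+", random_exon_chain(rng, max_exons=4, hi=2000), source="flnc")
            for k in range(40)
        ]
        ann = make_annotation([])
        counts = [len(build_loci(isoforms, ann, f)[0]) for f in (0.1, 0.2, 0.4, 0.8)]
        assert counts == sorted(counts)


class TestClassify:
    def test_skipped_exon_is_known_novel(self):
        iso = T("i1", [(0, 100), (400, 500)])  # skips the middle exon
        loci, _ = build_loci([iso], ANN)
        assert labels_of(loci)["i1"] == "known_novel"

    def test_retained_intron_is_known_novel(self):
        iso = T("i1", [(0, 300), (400, 500)])  # merges exons 1 and 2
        loci, _ = build_loci([iso], ANN)
        assert labels_of(loci)["i1"] == "known_novel"

    def test_new_splice_site_is_known_novel(self):
        iso = T("i1", [(0, 80), (200, 300), (400, 500)])  # shifted donor
        loci, _ = build_loci([iso], ANN)
        assert labels_of(loci)["i1"] == "known_novel"

    def test_single_exon_in_multiexon_gene_is_known_novel(self):
        iso = T("i1", [(0, 500)])
        loci, _ = build_loci([iso], ANN)
        assert labels_of(loci)["i1"] == "known_novel"

    def test_single_exon_matching_single_exon_gene(self):
        ann = make_annotation([T("r1", [(0, 500)], source="annotation")], gene_of={"r1": "g1"})
        loci, _ = build_loci([T("i1", [(10, 480)])], ann)
        assert labels_of(loci)["i1"] == "known_known"

    def test_truncated_copy_still_known_known(self):
        """Terminal-end differences alone do not make an isoform novel."""
        iso = T("i1", [(40, 100), (200, 300), (400, 470)])
        loci, _ = build_loci([iso], ANN)
        assert labels_of(loci)["i1"] == "known_known"


class TestPartition:
    def _toy_world(self):
        """3 genes; gene A rediscovered exactly + one exon-skipping variant."""
        ann = make_annotation(
            [
                T("rA", [(0, 100), (200, 300), (400, 500)], source="annotation"),
                T("rB", [(5000, 5100), (5200, 5300)], source="annotation"),
                T("rC", [(9000, 9100), (9200, 9300)], source="annotation"),
            ],
            gene_of={"rA": "gA", "rB": "gB", "rC": "gC"},
        )
        isoforms = [
            T("i1", [(0, 100), (200, 300), (400, 500)]),
            T("i2", [(0, 100), (400, 500)]),  # SKIP variant of gA
            T("i3", [(5000, 5100), (5200, 5300)]),
            T("i4", [(20_000, 20_500)]),
        ]
        return ann, isoforms

    def test_toy_partition(self):
        ann, isoforms = self._toy_world()
        loci, _ = build_loci(isoforms, ann)
        rep = partition_counts(loci)
        assert rep.known_novel == (1, 1)
        assert rep.known_known == (1, 2)  # gB's exact copy; gA counted as known_novel
        assert rep.novel == (1, 1)
        assert rep.total == (3, 4)

    def test_overlapping_mode_counts_gA_twice(self):
        ann, isoforms = self._toy_world()
        loci, _ = build_loci(isoforms, ann)
        rep = partition_counts(loci, "overlapping")
        assert rep.known_known[0] == 2  # gA has a known_known member too
        assert rep.known_novel[0] == 1
        assert rep.total == (3, 4)

    def test_isoform_totals_conserve(self):
        ann, isoforms = self._toy_world()
        loci, _ = build_loci(isoforms, ann)
        for mode in ("disjoint", "overlapping"):
            rep = partition_counts(loci, mode)
            assert rep.known_known[1] + rep.known_novel[1] + rep.novel[1] == rep.total[1]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            partition_counts([], "tiered")
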