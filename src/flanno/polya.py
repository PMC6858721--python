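"""PolyA-site clustering and alternative-polyadenylation (APA) calling.

Read 3' ends (the last aligned base in transcription orientation) are
assigned to gene loci, single-linkage clustered along the chromosome and
clusters with enough read support become polyA sites.  A gene with two or
more sites exhibits APA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import AlignedRead, Transcript, exonic_overlap
from .loci import Locus


@dataclass
class PolyASite:
    gene_id: str
    chrom: str
    strand: str
    position: int  # modal member position; ties resolved downstream
    support: int
    member_positions: list[int]


def assign_reads_to_loci(
    reads: Iterable[AlignedRead], loci: Sequence[Locus]
) -> dict[str, list[AlignedRead]]:
    """Best-exonic-overlap assignment of single-segment reads to loci.

    Reads overlapping no locus (or chimeric reads) are dropped — polyA sites
    are defined per gene.
    """
    by_key: dict[tuple[str, str], list[Locus]] = {}
    for locus in loci:
        by_key.setdefault((locus.chrom, locus.strand), []).append(locus)
    out: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.is_chimeric:
            continue
        t = read.as_transcript()
        best: Locus | None = None
        best_bp = 0
        for locus in by_key.get((t.chrom, t.strand), ()):
            if locus.end <= t.start or t.end <= locus.start:
                continue
            bp = max(
                (exonic_overlap(t, m).shared_bp for m in locus.transcripts()),
                default=0,
            )
            if bp > best_bp:
                best, best_bp = locus, bp
        if best is not None:
            out.setdefault(best.locus_id, []).append(read)
    return out


def _single_linkage(positions: list[int], radius: int) -> list[list[int]]:
    """Split sorted positions where the adjacent gap exceeds ``radius``."""
    clusters: list[list[int]] = []
    prev = None
    for p in sorted(positions):
        if prev is None or p - prev > radius:
            clusters.append([])
        clusters[-1].append(p)
        prev = p
    return clusters


def call_polya_sites(
    reads: Iterable[AlignedRead],
    loci: Sequence[Locus],
    cluster_radius: int = 24,
    min_support: int = 2,
) -> list[PolyASite]:
    """Cluster per-gene read 3' ends into supported polyA sites.

    The representative position is the mode of the cluster's member ends;
    ties go to the most downstream position in transcription orientation.
    """
    assigned = assign_reads_to_loci(reads, loci)
    locus_by_id = {locus.locus_id: locus for locus in loci}
    sites: list[PolyASite] = []
    for locus_id in sorted(assigned):
        locus = locus_by_id[locus_id]
        gene_id = locus.known_gene_id or locus.locus_id
        ends = [r.three_prime_end() for r in assigned[locus_id]]
        for cluster in _single_linkage(ends, cluster_radius):
            if len(cluster) < min_support:
                continue
            counts: dict[int, int] = {}
            for p in cluster:
                counts[p] = counts.get(p, 0) + 1
            downstream = (lambda p: p) if locus.strand == "+" else (lambda p: -p)
            position = max(counts, key=lambda p: (counts[p], downstream(p)))
            sites.append(
                PolyASite(
                    gene_id=gene_id,
                    chrom=locus.chrom,
                    strand=locus.strand,
                    position=position,
                    support=len(cluster),
                    member_positions=cluster,
                )
            )
    return sites


def call_apa(sites: Sequence[PolyASite]) -> dict[str, int]:
    """Summary counts: genes with sites, total sites, genes with >=2 sites (APA)."""
    per_gene: dict[str, int] = {}
    for s in sites:
        per_gene[s.gene_id] = per_gene.get(s.gene_id, 0) + 1
    return {
        "genes_with_sites": len(per_gene),
        "total_sites": len(sites),
        "apa_genes": sum(1 for n in per_gene.values() if n >= 2),
    }
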