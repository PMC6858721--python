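"""Fusion-transcript calling from multi-segment FLNC alignments.

A chimeric read becomes a fusion call when all four rules hold:

1. its aligned segments hit two or more distinct annotated gene loci and the
   breakpoint is clean — adjacent segments overlap by fewer than
   ``max_locus_overlap`` bp on read coordinates (a literal genomic-overlap
   reading is available via ``genomic_overlap_mode``);
2. every pair of hit loci lies on different chromosomes or more than
   ``min_distance`` bp apart;
3. the read's global PID >= ``min_global_pid`` and every segment's local PID
   >= ``min_local_pid``;
4. each hit locus' breakpoint-adjacent splice junction is supported by at
   least ``min_support_reads`` short reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import AlignedRead, Annotation, Intron, Segment, Transcript, exonic_overlap
from .filtering import JunctionSupportIndex


@dataclass
class FusionCall:
    read_id: str
    segments: tuple[Segment, ...]
    gene_ids: tuple[str, ...]
    fusion_type: str  # inter_chromosome | intra_chromosome
    illumina_support: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) < 2:
            raise ValueError(f"{self.read_id}: fusion with <2 distinct gene loci")


def _match_gene(seg: Segment, annotation: Annotation, gene_list: Sequence[tuple[str, list[Transcript]]]) -> tuple[str | None, int]:
    """Best-overlapping annotated gene for one segment (strand-agnostic)."""
    seg_t = Transcript("_seg", seg.chrom, seg.strand, seg.exons, source="flnc")
    best, best_bp = None, 0
    for gid, ts in gene_list:
        for t in ts:
            if t.chrom != seg.chrom:
                continue
            bp = exonic_overlap(seg_t, t).shared_bp
            if bp > best_bp:
                best, best_bp = gid, bp
    return best, best_bp


def _read_coord_overlaps(segments: Sequence[Segment]) -> list[int]:
    """Overlap in bp between adjacent segments on read coordinates.

    Segments without read intervals are taken as laid end to end (overlap 0).
    """
    out = []
    for a, b in zip(segments, segments[1:]):
        if a.read_end is None or b.read_start is None:
            out.append(0)
        else:
            out.append(max(0, a.read_end - b.read_start))
    return out


def _breakpoint_intron(seg: Segment, is_first: bool) -> Intron | None:
    """The segment's splice junction nearest the breakpoint (None if monoexonic)."""
    if len(seg.exons) < 2:
        return None
    if is_first:
        a, b = seg.exons[-2], seg.exons[-1]
    else:
        a, b = seg.exons[0], seg.exons[1]
    return Intron(seg.chrom, seg.strand, a.end, b.start)


def call_fusions(
    reads: Iterable[AlignedRead],
    annotation: Annotation,
    junction_reads: Mapping[Intron, int] | JunctionSupportIndex,
    max_locus_overlap: int = 10,
    min_distance: int = 50_000,
    min_global_pid: float = 10.0,
    min_local_pid: float = 90.0,
    min_support_reads: int = 2,
    genomic_overlap_mode: bool = False,
) -> list[FusionCall]:
    if isinstance(junction_reads, JunctionSupportIndex):
        support = junction_reads
    else:
        support = JunctionSupportIndex.from_counts(junction_reads)
    gene_list = sorted(annotation.genes().items())
    gene_spans = {gid: annotation.gene_span(gid) for gid, _ in gene_list}

    calls: list[FusionCall] = []
    for read in reads:
        if not read.is_chimeric:
            continue
        matches = [_match_gene(seg, annotation, gene_list) for seg in read.segments]
        hit_genes = [g for g, _ in matches if g is not None]
        if len(set(hit_genes)) < 2 or len(hit_genes) < len(read.segments):
            continue
        # rule 1: clean breakpoint
        if genomic_overlap_mode:
            # literal reading: each segment overlaps every *other* hit locus < N bp
            ok = True
            for (gid, _), seg in zip(matches, read.segments):
                seg_t = Transcript("_seg", seg.chrom, seg.strand, seg.exons, source="flnc")
                for other in set(hit_genes) - {gid}:
                    bp = sum(
                        exonic_overlap(seg_t, t).shared_bp
                        for t in dict(gene_list)[other]
                    )
                    if bp >= max_locus_overlap:
                        ok = False
            if not ok:
                continue
        else:
            if any(ov >= max_locus_overlap for ov in _read_coord_overlaps(read.segments)):
                continue
        # rule 2: loci well separated
        genes = sorted(set(hit_genes))
        separated = True
        for i, ga in enumerate(genes):
            for gb in genes[i + 1 :]:
                ca, _, sa, ea = gene_spans[ga]
                cb, _, sb, eb = gene_spans[gb]
                if ca == cb and max(sa, sb) - min(ea, eb) <= min_distance:
                    separated = False
        if not separated:
            continue
        # rule 3: identity thresholds
        if read.global_pid < min_global_pid:
            continue
        if any(seg.local_pid < min_local_pid for seg in read.segments):
            continue
        # rule 4: short-read support at each locus' breakpoint-adjacent junction
        supports = []
        supported = True
        for i, seg in enumerate(read.segments):
            j = _breakpoint_intron(seg, is_first=(i < len(read.segments) - 1))
            n = support.count(j) if j is not None else 0
            supports.append(n)
            if n < min_support_reads:
                supported = False
        if not supported:
            continue
        chroms = {seg.chrom for seg in read.segments}
        calls.append(
            FusionCall(
                read_id=read.read_id,
                segments=read.segments,
                gene_ids=tuple(hit_genes),
                fusion_type="inter_chromosome" if len(chroms) > 1 else "intra_chromosome",
                illumina_support=tuple(supports),
            )
        )
    return calls


def fusion_type_counts(calls: Sequence[FusionCall]) -> dict[str, int]:
    inter = sum(1 for c in calls if c.fusion_type == "inter_chromosome")
    intra = len(calls) - inter
    return {"inter": inter, "intra": intra, "total": len(calls)}
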