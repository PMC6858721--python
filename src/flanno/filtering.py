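"""Isoform retention rules for aligned FLNC reads.

Reads with identical splicing structure are grouped into candidate isoforms;
a candidate survives if it has >= 2 supporting reads, or any member read's
global percent identity exceeds 99%, or every splice junction of its
representative is backed by the short-read junction set or the reference
annotation (single-exon candidates satisfy the junction clause vacuously).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import AlignedRead, Annotation, Intron, Transcript, intron_chain, introns_of


@dataclass
class JunctionSupportIndex:
    """Short-read-supported splice junctions; membership is exact-boundary equality."""

    supported: set[Intron] = field(default_factory=set)
    counts: dict[Intron, int] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: Mapping[Intron, int]) -> "JunctionSupportIndex":
        return cls(set(counts), dict(counts))

    def __contains__(self, intron: Intron) -> bool:
        return intron in self.supported

    def count(self, intron: Intron) -> int:
        return self.counts.get(intron, 1 if intron in self.supported else 0)


@dataclass
class ReadGroup:
    """Reads sharing one splicing structure; the representative is the longest."""

    key: tuple
    reads: list[AlignedRead]

    @property
    def size(self) -> int:
        return len(self.reads)

    @property
    def representative(self) -> AlignedRead:
        return max(self.reads, key=lambda r: (r.as_transcript().exonic_length, r.read_id))

    @property
    def max_global_pid(self) -> float:
        return max(r.global_pid for r in self.reads)


def _cluster_1d(values: list[tuple[int, int]], fuzz: int) -> list[list[int]]:
    """Single-linkage on sorted scalars: a gap > fuzz starts a new cluster.

    ``values`` are (value, index) pairs; returns clusters of indices.
    """
    values = sorted(values)
    clusters: list[list[int]] = []
    prev = None
    for v, idx in values:
        if prev is None or v - prev > fuzz:
            clusters.append([])
        clusters[-1].append(idx)
        prev = v
    return clusters


def group_identical_structures(
    reads: Iterable[AlignedRead],
    fuzz: int | None = None,
    single_exon_fuzz: int = 10,
) -> list[ReadGroup]:
    """Group single-segment reads that represent the same isoform structure.

    Multi-exon reads share a group iff same chrom+strand and identical intron
    chains; when ``fuzz`` is given, terminal exon ends must additionally agree
    within ``fuzz`` bp (the default, ``fuzz=None``, ignores terminal ends, the
    usual long-read collapse convention).  Single-exon reads are clustered by
    both endpoints within ``single_exon_fuzz`` bp (single linkage).
    """
    reads = list(reads)
    for r in reads:
        if r.is_chimeric:
            raise ValueError(
                f"{r.read_id}: multi-segment reads must be routed to fusion calling"
            )
    buckets: dict[tuple, list[AlignedRead]] = {}
    for r in reads:
        seg = r.segment
        buckets.setdefault(
            (seg.chrom, seg.strand, intron_chain(r.as_transcript())), []
        ).append(r)

    groups: list[ReadGroup] = []
    for key, members in buckets.items():
        chrom, strand, chain = key
        if not chain:  # single-exon: positional tolerance on both ends
            subclusters = _split_by_ends(members, single_exon_fuzz, single_exon_fuzz)
        elif fuzz is not None:
            subclusters = _split_by_ends(members, fuzz, fuzz)
        else:
            subclusters = [members]
        for i, sub in enumerate(subclusters):
            groups.append(ReadGroup(key + (i,), sub))
    groups.sort(key=lambda g: (g.key[0], g.representative.as_transcript().start, str(g.key)))
    return groups


def _split_by_ends(
    members: list[AlignedRead], start_fuzz: int, end_fuzz: int
) -> list[list[AlignedRead]]:
    starts = [(r.as_transcript().start, i) for i, r in enumerate(members)]
    out: list[list[AlignedRead]] = []
    for cluster in _cluster_1d(starts, start_fuzz):
        ends = [(members[i].as_transcript().end, i) for i in cluster]
        for sub in _cluster_1d(ends, end_fuzz):
            out.append([members[i] for i in sub])
    return out


def retained_with_groups(
    groups: Sequence[ReadGroup],
    junctions: JunctionSupportIndex,
    annotation: Annotation | None = None,
    min_reads: int = 2,
    min_pid: float = 99.0,
    id_prefix: str = "iso",
) -> list[tuple[Transcript, ReadGroup]]:
    """Apply the three OR-ed retention clauses, keeping isoform -> reads links.

    Clauses: group size >= ``min_reads``; any member global PID strictly above
    ``min_pid``; every intron of the representative present in the short-read
    junction set or among annotated introns (vacuous for single-exon reps).
    """
    annotated = annotation.all_introns() if annotation is not None else set()
    out: list[tuple[Transcript, ReadGroup]] = []
    for group in groups:
        rep = group.representative.as_transcript()
        keep = (
            group.size >= min_reads
            or group.max_global_pid > min_pid
            or all(j in junctions or j in annotated for j in introns_of(rep))
        )
        if keep:
            tid = f"{id_prefix}_{len(out) + 1:06d}"
            out.append(
                (Transcript(tid, rep.chrom, rep.strand, rep.exons, source="flnc"), group)
            )
    return out


def retain(
    groups: Sequence[ReadGroup],
    junctions: JunctionSupportIndex,
    annotation: Annotation | None = None,
    min_reads: int = 2,
    min_pid: float = 99.0,
    id_prefix: str = "iso",
) -> list[Transcript]:
    """One collapsed Transcript per retained read group (see retained_with_groups)."""
    return [
        t
        for t, _ in retained_with_groups(
            groups, junctions, annotation, min_reads, min_pid, id_prefix
        )
    ]
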