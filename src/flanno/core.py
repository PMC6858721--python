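"""Genomic coordinate types and interval arithmetic.

All internal coordinates are 0-based half-open ``[start, end)``; the GFF3
reader/writer converts to and from the 1-based inclusive convention at the
boundary.  A :class:`Transcript` is the universal unit: reference annotation
entries, collapsed FLNC isoforms and merged-library records all share it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple


class Exon(NamedTuple):
    """Half-open genomic interval of one exon."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class Intron(NamedTuple):
    """Half-open genomic span between two consecutive exons (a splice junction)."""

    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig; sequence is upper-cased on construction."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.chrom_id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence on ``[start, end)``; out-of-bounds lookups are errors."""
        if start < 0 or end > len(self.sequence) or start >= end:
            raise IndexError(
                f"{self.chrom_id}:{start}-{end} outside [0, {len(self.sequence)})"
            )
        return self.sequence[start:end]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A strand-aware exon chain on one chromosome.

    ``source`` records provenance: ``annotation`` (reference), ``flnc``
    (collapsed long-read isoform) or ``merged`` (library union).
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    source: str = "annotation"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")
        exons = tuple(Exon(*e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.id}: transcript with no exons")
        prev_end = None
        for e in exons:
            if e.start >= e.end:
                raise ValueError(f"{self.id}: exon {e} has start >= end")
            if prev_end is not None and e.start <= prev_end:
                raise ValueError(
                    f"{self.id}: exons overlap or touch at {prev_end}/{e.start}"
                )
            prev_end = e.end

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def three_prime_end(self) -> int:
        """Genomic position of the final transcribed base (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start


def introns_of(t: Transcript) -> list[Intron]:
    """Splice junctions of a transcript: n exons -> n-1 introns."""
    return [
        Intron(t.chrom, t.strand, a.end, b.start)
        for a, b in zip(t.exons, t.exons[1:])
    ]


def intron_chain(t: Transcript) -> tuple[tuple[int, int], ...]:
    """The (start, end) intron chain — the collapse/identity key for multi-exon isoforms."""
    return tuple((a.end, b.start) for a, b in zip(t.exons, t.exons[1:]))


@dataclass
class Annotation:
    """Reference gene models: transcripts, their gene assignment, optional CDS spans."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)
    cds_span: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid in self.transcripts:
            if tid not in self.gene_of:
                raise ValueError(f"transcript {tid} has no gene assignment")
        by_gene: dict[str, Transcript] = {}
        for tid, gid in self.gene_of.items():
            t = self.transcripts[tid]
            ref = by_gene.setdefault(gid, t)
            if (ref.chrom, ref.strand) != (t.chrom, t.strand):
                raise ValueError(f"gene {gid}: transcripts on different chrom/strand")

    def genes(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for tid, gid in self.gene_of.items():
            out.setdefault(gid, []).append(self.transcripts[tid])
        return out

    def gene_span(self, gene_id: str) -> tuple[str, str, int, int]:
        ts = [self.transcripts[t] for t, g in self.gene_of.items() if g == gene_id]
        if not ts:
            raise KeyError(gene_id)
        return (
            ts[0].chrom,
            ts[0].strand,
            min(t.start for t in ts),
            max(t.end for t in ts),
        )

    def all_introns(self) -> set[Intron]:
        out: set[Intron] = set()
        for t in self.transcripts.values():
            out.update(introns_of(t))
        return out

    def __len__(self) -> int:
        return len(self.transcripts)


class OverlapReport(NamedTuple):
    """Exon-chain intersection between two transcripts.

    ``frac_a``/``frac_b`` are the shared exonic base pairs as a fraction of
    each transcript's own exonic length; ``max_single_exon_frac`` is the best
    single exon-pair overlap relative to the shorter exon of the pair.
    """

    shared_bp: int
    frac_a: float
    frac_b: float
    max_single_exon_frac: float


_ZERO_OVERLAP = OverlapReport(0, 0.0, 0.0, 0.0)


def exonic_overlap(a: Transcript, b: Transcript) -> OverlapReport:
    """Exonic overlap between two transcripts (all-zero if on different chroms)."""
    if a.chrom != b.chrom:
        return _ZERO_OVERLAP
    shared = 0
    max_pair = 0.0
    # exon lists are sorted and disjoint -> linear merge
    i = j = 0
    ea, eb = a.exons, b.exons
    while i < len(ea) and j < len(eb):
        lo = max(ea[i].start, eb[j].start)
        hi = min(ea[i].end, eb[j].end)
        if hi > lo:
            shared += hi - lo
            frac = (hi - lo) / min(ea[i].length, eb[j].length)
            if frac > max_pair:
                max_pair = frac
        if ea[i].end <= eb[j].end:
            i += 1
        else:
            j += 1
    if shared == 0:
        return _ZERO_OVERLAP
    return OverlapReport(
        shared, shared / a.exonic_length, shared / b.exonic_length, max_pair
    )


# ---------------------------------------------------------------------------
# aligned reads


@dataclass(frozen=True)
class Segment:
    """One aligned block of a read: an exon chain plus its alignment identity.

    ``read_start``/``read_end`` locate the segment on read coordinates; they are
    optional and only consulted by the fusion caller's breakpoint rule.
    """

    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    local_pid: float = 100.0
    read_start: int | None = None
    read_end: int | None = None

    def as_transcript(self, read_id: str) -> Transcript:
        return Transcript(read_id, self.chrom, self.strand, self.exons, source="flnc")


@dataclass(frozen=True)
class AlignedRead:
    """One FLNC read's spliced alignment: >=1 genomic segments + identity values."""

    read_id: str
    segments: tuple[Segment, ...]
    global_pid: float = 100.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"{self.read_id}: read with no segments")

    @property
    def is_chimeric(self) -> bool:
        return len(self.segments) > 1

    @property
    def segment(self) -> Segment:
        if self.is_chimeric:
            raise ValueError(f"{self.read_id}: multi-segment read")
        return self.segments[0]

    def as_transcript(self) -> Transcript:
        return self.segment.as_transcript(self.read_id)

    def three_prime_end(self) -> int:
        """Last aligned base in transcription orientation (of the final segment)."""
        seg = self.segments[-1]
        return seg.exons[-1].end - 1 if seg.strand == "+" else seg.exons[0].start


def transcripts_iter(source: Iterable[Transcript] | Mapping[str, Transcript]) -> Iterator[Transcript]:
    if isinstance(source, Mapping):
        return iter(source.values())
    return iter(source)
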