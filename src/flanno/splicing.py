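"""Alternative-splicing event typing, splice-site dinucleotide census and
splice-junction genomic-context assignment.

Event taxonomy (detected between isoform pairs of one locus):

- SKIP / MSKIP — one (/multiple consecutive) exon(s) present in one isoform
  are absent from the other, with the flanking junction outer boundaries
  matching exactly;
- IR / MIR     — one isoform's exon exactly spans one (/multiple) intron(s)
  of the other;
- AE           — two overlapping introns share exactly one boundary, the
  other (an internal exon end) differs;
- XSKIP/XMSKIP/XIR/XMIR/XAE — the same topologies with boundary matching
  relaxed to <= ``fuzz`` bp (events that already match exactly keep their
  plain type, so ``fuzz=0`` leaves every X category empty and increasing
  ``fuzz`` can only add events).

Events are deduplicated by (type, coordinates) within a locus; pure TSS/TTS
differences are never events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import GenomeSequence, Annotation, Intron, Transcript, introns_of, reverse_complement
from .loci import Locus

AS_TYPES = ("SKIP", "MSKIP", "IR", "MIR", "AE", "XSKIP", "XMSKIP", "XIR", "XMIR", "XAE")


@dataclass(frozen=True)
class ASEvent:
    locus_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    inclusion_id: str
    exclusion_id: str

    def __post_init__(self) -> None:
        if self.event_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.event_type!r}")

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _skip_candidates(excl: Transcript, incl: Transcript, tol: int):
    """Exons of ``incl`` skipped inside an intron of ``excl`` (flanks within tol)."""
    out = []
    for a, b in zip(excl.exons, excl.exons[1:]):
        d, c = a.end, b.start  # the exclusion intron
        inside = [
            k
            for k, e in enumerate(incl.exons)
            if e.start > d and e.end < c
        ]
        if not inside or inside != list(range(inside[0], inside[-1] + 1)):
            continue
        j1, j2 = inside[0], inside[-1]
        if j1 - 1 < 0 or j2 + 1 >= incl.n_exons:
            continue
        if abs(incl.exons[j1 - 1].end - d) <= tol and abs(incl.exons[j2 + 1].start - c) <= tol:
            n_skipped = j2 - j1 + 1
            out.append(
                (
                    "SKIP" if n_skipped == 1 else "MSKIP",
                    incl.exons[j1].start,
                    incl.exons[j2].end,
                )
            )
    return out


def _ir_candidates(retainer: Transcript, spliced: Transcript, tol: int):
    """Exons of ``retainer`` spanning intron(s) of ``spliced`` (ends within tol)."""
    out = []
    sp_introns = introns_of(spliced)
    for ex in retainer.exons:
        inside = [
            j for j in sp_introns if j.start > ex.start and j.end < ex.end
        ]
        if not inside:
            continue
        # flanking exon outer ends of the spliced isoform must match the exon
        first, last = inside[0], inside[-1]
        left = next((e for e in spliced.exons if e.end == first.start), None)
        right = next((e for e in spliced.exons if e.start == last.end), None)
        if left is None or right is None:
            continue
        if abs(left.start - ex.start) <= tol and abs(right.end - ex.end) <= tol:
            out.append(
                ("IR" if len(inside) == 1 else "MIR", first.start, last.end)
            )
    return out


def _ae_candidates(a: Transcript, b: Transcript, tol: int):
    """Overlapping intron pairs where one boundary matches (within tol) and the
    other differs; the event span covers the differing boundary pair."""
    out = []
    a_introns = introns_of(a)
    b_introns = introns_of(b)
    for ia in a_introns:
        for ib in b_introns:
            if ia.start >= ib.end or ib.start >= ia.end:
                continue
            ds, de = abs(ia.start - ib.start), abs(ia.end - ib.end)
            if min(ds, de) > tol or max(ds, de) == 0:
                continue
            # a skipped exon inside either intron explains the difference -> SKIP territory
            if any(e.start > ia.start and e.end < ia.end for e in b.exons):
                continue
            if any(e.start > ib.start and e.end < ib.end for e in a.exons):
                continue
            lo_s, hi_s = sorted((ia.start, ib.start))
            lo_e, hi_e = sorted((ia.end, ib.end))
            span = (lo_e, hi_e) if de >= ds else (lo_s, hi_s)
            out.append(("AE", span[0], span[1]))
    return out


def _pair_events(a: Transcript, b: Transcript, fuzz: int) -> list[tuple[str, int, int, str, str]]:
    """Typed events between one unordered isoform pair.

    Candidates detected at ``fuzz`` tolerance but failing exact matching get
    the X-prefixed type; exact candidates keep the plain type.
    """
    events: list[tuple[str, int, int, str, str]] = []

    def _directional(detector, x, y, inclusion, exclusion):
        exact = set(detector(x, y, 0))
        fuzzy = detector(x, y, fuzz) if fuzz > 0 else []
        for typ, s, e in sorted(exact):
            events.append((typ, s, e, inclusion.id, exclusion.id))
        for cand in fuzzy:
            if cand not in exact:
                typ, s, e = cand
                events.append(("X" + typ, s, e, inclusion.id, exclusion.id))

    _directional(_skip_candidates, a, b, b, a)  # incl=b carries the extra exon(s)
    _directional(_skip_candidates, b, a, a, b)
    _directional(_ir_candidates, a, b, a, b)  # incl=a retains the intron(s)
    _directional(_ir_candidates, b, a, b, a)

    pair = tuple(sorted((a.id, b.id)))
    exact_ae = set(_ae_candidates(a, b, 0))
    for typ, s, e in sorted(exact_ae):
        events.append((typ, s, e, pair[0], pair[1]))
    if fuzz > 0:
        for cand in _ae_candidates(a, b, fuzz):
            if cand not in exact_ae:
                typ, s, e = cand
                events.append(("X" + typ, s, e, pair[0], pair[1]))
    return events


def detect_as_events(locus: Locus, fuzz: int = 10) -> list[ASEvent]:
    """All deduplicated AS events among the locus' isoforms (discovered and
    reference alike), reported once per (type, coordinates)."""
    ts = locus.transcripts()
    seen: dict[tuple, ASEvent] = {}
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            for typ, s, e, inc, exc in _pair_events(ts[i], ts[j], fuzz):
                key = (typ, s, e)
                if key not in seen:
                    seen[key] = ASEvent(locus.locus_id, typ, locus.chrom, s, e, inc, exc)
    return sorted(seen.values(), key=lambda ev: (ev.start, ev.end, ev.event_type))


def as_type_percentages(events: Sequence[ASEvent]) -> dict[str, float]:
    """Fraction of events per type (empty mapping for no events)."""
    if not events:
        return {}
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.event_type] = counts.get(ev.event_type, 0) + 1
    total = len(events)
    return {t: counts[t] / total for t in sorted(counts)}


def as_gene_counts(loci_events: Mapping[str, Sequence[ASEvent]]) -> dict[str, int]:
    """Number of genes (loci) exhibiting each AS type — the paper-style counter."""
    out: dict[str, int] = {}
    for _locus_id, events in loci_events.items():
        for typ in {ev.event_type for ev in events}:
            out[typ] = out.get(typ, 0) + 1
    return out


# ---------------------------------------------------------------------------
# splice-site dinucleotide census


@dataclass
class SpliceSiteCensus:
    counts: dict[str, int] = field(default_factory=lambda: {k: 0 for k in ("GT-AG", "GC-AG", "AT-AC", "other")})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / tot for k, v in self.counts.items()}


def classify_dinucleotides(donor: str, acceptor: str) -> str:
    pair = f"{donor}-{acceptor}"
    return pair if pair in ("GT-AG", "GC-AG", "AT-AC") else "other"


def intron_dinucleotides(j: Intron, genome: Mapping[str, GenomeSequence]) -> tuple[str, str]:
    """(donor, acceptor) 2-mers in transcription orientation; N stays literal."""
    seq = genome[j.chrom]
    left = seq.fetch(j.start, j.start + 2)
    right = seq.fetch(j.end - 2, j.end)
    if j.strand == "+":
        return left, right
    return reverse_complement(right), reverse_complement(left)


def splice_site_census(
    transcripts: Iterable[Transcript], genome: Mapping[str, GenomeSequence]
) -> SpliceSiteCensus:
    """Donor-acceptor census over the unique splice junctions of the input."""
    census = SpliceSiteCensus()
    seen: set[Intron] = set()
    for t in transcripts:
        for j in introns_of(t):
            if j in seen:
                continue
            seen.add(j)
            if j.chrom not in genome or j.start < 0 or j.end > len(genome[j.chrom]):
                raise ValueError(f"intron of {t.id} outside genome bounds: {j}")
            donor, acceptor = intron_dinucleotides(j, genome)
            census.counts[classify_dinucleotides(donor, acceptor)] += 1
    return census


# ---------------------------------------------------------------------------
# SJ genomic context


@dataclass
class SJContextReport:
    counts: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in ("CDS", "5'UTR", "3'UTR", "intron", "intergenic")}
    )


def _donor_position(j: Intron) -> int:
    return j.start if j.strand == "+" else j.end - 1


def sj_context(junctions: Iterable[Intron], annotation: Annotation) -> SJContextReport:
    """Assign each junction's donor position to one genomic context.

    Precedence CDS > UTR > intron > intergenic, across all annotated
    transcripts of the chromosome (either strand).  UTR side follows the
    host transcript's strand relative to its CDS span; transcripts without a
    CDS fall back to the transcript midpoint.
    """
    by_chrom: dict[str, list[Transcript]] = {}
    for t in annotation.transcripts.values():
        by_chrom.setdefault(t.chrom, []).append(t)
    report = SJContextReport()
    for j in junctions:
        p = _donor_position(j)
        best = "intergenic"
        rank = {"CDS": 0, "5'UTR": 1, "3'UTR": 1, "intron": 2, "intergenic": 3}
        for t in by_chrom.get(j.chrom, ()):
            if not (t.start <= p < t.end):
                continue
            cds = annotation.cds_span.get(t.id)
            exonic = any(e.start <= p < e.end for e in t.exons)
            if exonic and cds and cds[0] <= p < cds[1]:
                region = "CDS"
            elif exonic:
                if cds:
                    upstream = p < cds[0]
                else:
                    upstream = p < (t.start + t.end) // 2
                if t.strand == "-":
                    upstream = not upstream
                region = "5'UTR" if upstream else "3'UTR"
            else:
                region = "intron"
            if rank[region] < rank[best]:
                best = region
        report.counts[best] += 1
    return report


# ---------------------------------------------------------------------------
# exon counts of AS vs non-AS genes


def exon_count_by_as_status(
    loci: Sequence[Locus], fuzz: int = 10
) -> dict[str, list[int]]:
    """Per-gene maximum isoform exon counts, split by whether the gene shows
    at least one AS event among its isoforms."""
    out: dict[str, list[int]] = {"as_genes": [], "non_as_genes": []}
    for locus in loci:
        ts = locus.transcripts()
        events = detect_as_events(locus, fuzz) if len(ts) > 1 else []
        key = "as_genes" if events else "non_as_genes"
        out[key].append(max(t.n_exons for t in ts))
    return out
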